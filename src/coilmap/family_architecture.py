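"""Domain-architecture classification from coiled-coil probability tracks.

Each sequence is represented by a per-residue coiled-coil probability track
(the output format of sequence-based CC predictors) plus optional predicted
heptad positions and helix-turn-helix (HTH) domain intervals.  Tracks are
segmented at the medium (p ≥ 0.5) and high (p ≥ 0.75) confidence thresholds,
classified for the HTH-followed-by-CC architecture, and summarized into
family-level fractions, including the fraction of CC domains whose predicted
register departs from the canonical heptad pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heptad_register import HeptadString, detect_discontinuities

__all__ = [
    "CCTrack",
    "ArchitectureFlags",
    "ArchitectureSummary",
    "segment_track",
    "classify_architecture",
    "family_summary",
    "P_MEDIUM",
    "P_HIGH",
]

#: Confidence thresholds on the per-residue coiled-coil probability.
P_MEDIUM = 0.5
P_HIGH = 0.75

#: Default minimal CC segment length (two heptads) and bridgeable gap.
MIN_SEGMENT_LEN = 14
MAX_GAP = 3


@dataclass
class CCTrack:
    """One sequence's coiled-coil probability track and annotations."""

    track_id: str
    probs: np.ndarray
    heptad: list[str] | None = None  # per-residue position, '-' unassigned
    hth_intervals: list[tuple[int, int]] = field(default_factory=list)
    labels: dict = field(default_factory=dict)  # planted ground truth, if any

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities outside [0, 1]")
        if self.heptad is not None and len(self.heptad) != len(self.probs):
            raise ValueError("heptad annotation length mismatch")
        for lo, hi in self.hth_intervals:
            if not (1 <= lo <= hi <= len(self.probs)):
                raise ValueError(f"HTH interval ({lo}, {hi}) outside track")

    @property
    def length(self) -> int:
        return len(self.probs)


@dataclass
class ArchitectureFlags:
    """Per-track architecture classification."""

    has_hth: bool
    cc_medium: bool
    cc_high: bool
    cc_cterminal_to_hth: bool
    cc_overlaps_hth: bool
    noncanonical: bool


@dataclass
class ArchitectureSummary:
    """Family-level fractions over a set of tracks."""

    n_sequences: int
    frac_cc_medium: float
    frac_cc_high: float
    frac_cc_cterminal: float
    frac_noncanonical: float  # among CC-containing (medium) tracks

    def __post_init__(self) -> None:
        for name in ("frac_cc_medium", "frac_cc_high", "frac_cc_cterminal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.frac_cc_high > self.frac_cc_medium + 1e-12:
            raise ValueError("high-confidence fraction exceeds medium fraction")


def segment_track(
    probs: np.ndarray,
    threshold: float,
    min_len: int = MIN_SEGMENT_LEN,
    max_gap: int = MAX_GAP,
) -> list[tuple[int, int]]:
    """Maximal runs of residues with p ≥ threshold, as 1-based intervals.

    Sub-threshold gaps of at most ``max_gap`` residues between runs are
    bridged before the ``min_len`` filter is applied.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold outside [0, 1]")
    probs = np.asarray(probs, dtype=float)
    above = probs >= threshold
    runs: list[list[int]] = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        if runs and (i - runs[-1][1]) <= max_gap + 1:
            runs[-1][1] = j
        else:
            runs.append([i, j])
        i = j + 1
    return [(a + 1, b + 1) for a, b in runs if b - a + 1 >= min_len]


def classify_architecture(
    track: CCTrack,
    p_med: float = P_MEDIUM,
    p_high: float = P_HIGH,
    min_len: int = MIN_SEGMENT_LEN,
    max_gap: int = MAX_GAP,
) -> ArchitectureFlags:
    """Classify one track's domain architecture.

    ``cc_cterminal_to_hth`` requires a high-confidence segment starting
    strictly after the end of the last HTH interval; high-confidence segments
    overlapping an HTH interval set ``cc_overlaps_hth`` instead of being
    silently counted.  ``noncanonical`` runs discontinuity detection on the
    predicted register restricted to the medium-confidence CC segments.
    """
    med = segment_track(track.probs, p_med, min_len, max_gap)
    high = segment_track(track.probs, p_high, min_len, max_gap)
    has_hth = bool(track.hth_intervals)
    hth_end = max((hi for _, hi in track.hth_intervals), default=0)
    cterm = any(lo > hth_end for lo, hi in high) if has_hth else False
    overlaps = any(
        lo <= h_hi and hi >= h_lo
        for lo, hi in high
        for h_lo, h_hi in track.hth_intervals
    )
    noncanonical = False
    if track.heptad is not None and med:
        masked = ["-"] * track.length
        for lo, hi in med:
            masked[lo - 1 : hi] = track.heptad[lo - 1 : hi]
        if sum(p != "-" for p in masked) >= 2:
            reg = HeptadString(positions="".join(masked), source="prediction")
            noncanonical = bool(detect_discontinuities(reg))
    return ArchitectureFlags(
        has_hth=has_hth,
        cc_medium=bool(med),
        cc_high=bool(high),
        cc_cterminal_to_hth=cterm,
        cc_overlaps_hth=overlaps,
        noncanonical=noncanonical,
    )


def family_summary(
    tracks: list[CCTrack],
    p_med: float = P_MEDIUM,
    p_high: float = P_HIGH,
    min_len: int = MIN_SEGMENT_LEN,
    max_gap: int = MAX_GAP,
) -> ArchitectureSummary:
    """Exact fractions of architecture flags over the input tracks.

    The non-canonical fraction is computed over CC-containing (medium
    confidence) tracks only; it is 0.0 when no track contains a CC segment.
    """
    if not tracks:
        raise ValueError("empty track set")
    flags = [
        classify_architecture(t, p_med, p_high, min_len, max_gap) for t in tracks
    ]
    n = len(flags)
    n_med = sum(f.cc_medium for f in flags)
    n_high = sum(f.cc_high for f in flags)
    n_ct = sum(f.cc_cterminal_to_hth for f in flags)
    n_nc = sum(f.noncanonical for f in flags if f.cc_medium)
    return ArchitectureSummary(
        n_sequences=n,
        frac_cc_medium=n_med / n,
        frac_cc_high=n_high / n,
        frac_cc_cterminal=n_ct / n,
        frac_noncanonical=(n_nc / n_med) if n_med else 0.0,
    )
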