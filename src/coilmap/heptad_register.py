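"""Heptad register assignment and discontinuity detection.

Structure-derived Crick phases or sequence-based predictions are converted to
per-residue heptad positions (a–g).  A discontinuity is any transition where
the register does not advance by exactly one position; the register advance
observed at the break classifies it (advance 4 = stutter, advance 3 =
stammer), following the classical description of heptad-pattern breaks as
4- or 3-residue insertions.  A sequence containing any discontinuity is
non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bundle_geometry import PhaseTrace

__all__ = [
    "HeptadString",
    "Discontinuity",
    "phase_to_heptad",
    "detect_discontinuities",
    "classify_canonical",
    "HEPTAD",
    "PHASE_BIN",
]

HEPTAD = "abcdefg"
PHASE_BIN = 360.0 / 7.0

#: Unassigned runs up to this length are bridged when testing succession;
#: longer runs split the register into independent segments.
DEFAULT_GAP_TOLERANCE = 3


@dataclass
class Discontinuity:
    """A break in the heptad pattern.

    ``position`` is the 1-based residue index of the first residue after the
    break; ``shift`` is the observed register advance (mod 7) across the
    break, normalized to an adjacent-residue step (canonical advance is 1 and
    is never reported).
    """

    position: int
    shift: int
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.shift % 7 == 1:
            raise ValueError("shift of 1 is the canonical succession")
        self.shift %= 7
        self.label = {4: "stutter", 3: "stammer"}.get(self.shift, "other")


@dataclass
class HeptadString:
    """Per-residue heptad positions with detected discontinuity events."""

    positions: str  # over 'abcdefg' plus '-' for unassigned
    source: str = "structure"  # or "prediction"
    events: list[Discontinuity] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.positions) - set(HEPTAD + "-")
        if bad:
            raise ValueError(f"invalid register symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.positions)


def phase_to_heptad(
    phase: PhaseTrace | np.ndarray, anchor: float = 0.0, source: str = "structure"
) -> HeptadString:
    """Assign each residue to one of seven equal 51.43° Crick-phase bins.

    The bin [0°, 51.43°) maps to position ``a`` and the bin [308.57°, 360°)
    to ``d``: the two core-facing positions straddle phase 0 (the direction
    toward the bundle axis).  Because the phase advances two bins per residue,
    bins follow the order a, e, b, f, c, g, d around the circle (bin k maps
    to position 4k mod 7).  ``anchor`` rotates the bin frame (degrees) for
    alternative conventions.  Residues without a defined phase are unassigned.
    """
    values = phase.values if isinstance(phase, PhaseTrace) else np.asarray(phase)
    if len(values) == 0 or not np.any(np.isfinite(values)):
        raise ValueError("empty phase trace")
    out = []
    for v in values:
        if not np.isfinite(v):
            out.append("-")
            continue
        k = int(np.floor(((v - anchor) % 360.0) / PHASE_BIN)) % 7
        out.append(HEPTAD[(4 * k) % 7])
    return HeptadString(positions="".join(out), source=source)


def merge_events(
    events: list[Discontinuity], window: int = 4
) -> list[Discontinuity]:
    """Combine raw events closer than ``window`` residues into net events.

    Around a genuine register break measured from coordinates, the perturbed
    axis estimate can smear one planted discontinuity into a short cluster of
    raw transitions.  The net register offset across a cluster is the sum of
    the individual offsets (each event's shift minus the canonical advance of
    1), so clusters are combined into a single event with
    shift = (Σ(shift_i − 1) + 1) mod 7 at the rounded mean position.
    Clusters whose net shift is canonical (≡ 1) cancel and are dropped.
    """
    if not events:
        return []
    clusters: list[list[Discontinuity]] = [[events[0]]]
    for ev in events[1:]:
        if ev.position - clusters[-1][-1].position <= window:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    merged = []
    for cl in clusters:
        net = (sum(e.shift - 1 for e in cl) + 1) % 7
        if net == 1:
            continue
        pos = int(round(np.mean([e.position for e in cl])))
        merged.append(Discontinuity(position=pos, shift=net))
    return merged


def detect_discontinuities(
    register: HeptadString | str,
    max_gap: int = DEFAULT_GAP_TOLERANCE,
    merge_window: int = 0,
) -> list[Discontinuity]:
    """Find all transitions that break the canonical a→b→…→g→a succession.

    Unassigned runs of length ≤ ``max_gap`` are bridged: across a bridged gap
    of g unassigned residues the expected advance is g + 1 positions (mod 7).
    Longer runs split the register into independent segments and no event is
    emitted at the seam.  The reported shift is normalized to the equivalent
    adjacent-residue advance, so a planted shift is recovered regardless of
    an intervening short gap.

    ``merge_window`` > 0 additionally combines raw events closer than that
    many residues into single net events (see :func:`merge_events`);
    recommended (window 4) for registers measured from coordinates, where one
    planted break can smear into a short event cluster.  The default (0)
    reports every non-canonical transition individually.
    """
    positions = register.positions if isinstance(register, HeptadString) else register
    assigned = [(i, p) for i, p in enumerate(positions) if p != "-"]
    if len(assigned) < 2:
        raise ValueError("register needs at least 2 assigned residues")
    events: list[Discontinuity] = []
    for (i, a), (j, b) in zip(assigned, assigned[1:]):
        gap = j - i - 1
        if gap > max_gap:
            continue  # segment boundary: independent register phases
        expected = (j - i) % 7
        observed = (HEPTAD.index(b) - HEPTAD.index(a)) % 7
        if observed != expected:
            shift = (observed - expected + 1) % 7
            events.append(Discontinuity(position=j + 1, shift=shift))
    if merge_window > 0:
        events = merge_events(events, window=merge_window)
    if isinstance(register, HeptadString):
        register.events = events
    return events


def classify_canonical(
    register: HeptadString | str, max_gap: int = DEFAULT_GAP_TOLERANCE
) -> str:
    """'canonical' iff the register contains no heptad discontinuity."""
    return "non-canonical" if detect_discontinuities(register, max_gap) else "canonical"
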