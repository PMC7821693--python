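"""Analytic generation of two-helix coiled-coil bundles and related fixtures.

The generator realizes the Crick parameterization of an α-helical bundle: each
chain's local helix axis winds around a common superhelical (bundle) axis with
angular frequency ``superhelix_freq`` (ω0, degrees per residue; negative =
left-handed supercoil), while the Cα atoms wind around the local helix axis
with frequency ``helix_freq`` (ω1).  The minor-helix phase is measured in the
rotating frame whose reference direction points from the local helix axis
toward the bundle axis, so a canonical dimer with ω1 = 720/7 °/residue repeats
its heptad register exactly every seven residues.

Local distortions (stutters, stammers, unwound and right-handed stretches) are
planted as piecewise parameter overrides, which gives every generated bundle
an exact per-residue ground truth for round-trip testing of the measurement
code.

The module also synthesizes the remaining study inputs: families of
coiled-coil probability tracks with planted domain architectures, sequences
with controlled heptad-position composition, and two-state thermal melting
curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SegmentOverride",
    "CrickParams",
    "Chain",
    "Bundle",
    "MeltCurve",
    "CANONICAL_HEPTAD_FREQ",
    "phase_for_position",
    "generate_crick_bundle",
    "inject_distortion",
    "generate_family",
    "generate_melt_curve",
    "assign_sequence",
]

#: Minor-helix frequency of a canonical coiled coil: two full turns per heptad.
CANONICAL_HEPTAD_FREQ = 720.0 / 7.0

#: Width of one heptad phase bin in degrees.
PHASE_BIN = 360.0 / 7.0

HEPTAD = "abcdefg"


def phase_for_position(position: str) -> float:
    """Crick phase (degrees) at the center of the bin of heptad ``position``.

    Position ``a`` is centered at +360/14° and ``d`` at −360/14° (mod 360);
    the two core-facing positions straddle the direction toward the bundle
    axis (phase 0).  Consecutive residues advance the phase by ω1, i.e. two
    bins, so the seven positions occur in phase order a, e, b, f, c, g, d.
    """
    idx = HEPTAD.index(position)
    # letter index -> bin index: 2 bins per letter step (mod 7)
    bin_idx = (2 * idx) % 7
    return (bin_idx * PHASE_BIN + PHASE_BIN / 2.0) % 360.0


@dataclass(frozen=True)
class SegmentOverride:
    """Piecewise parameter override on a closed, 1-based residue interval.

    ``phase_jump`` (degrees) is added to the minor-helix phase of every
    residue from ``start`` on; it models register discontinuities.
    """

    start: int
    end: int
    superhelix_freq: float | None = None
    helix_freq: float | None = None
    phase_jump: float = 0.0


@dataclass(frozen=True)
class CrickParams:
    """Analytic description of an ideal or locally distorted two-helix bundle.

    Angles in degrees per residue, lengths in Å.  Defaults are standard
    literature values for a parallel dimeric coiled coil.
    """

    n_residues: int = 251
    n_chains: int = 2
    superhelix_radius: float = 4.9
    helix_radius: float = 2.26
    superhelix_freq: float = -3.6
    helix_freq: float = CANONICAL_HEPTAD_FREQ
    crick_phase: float = phase_for_position("a")
    rise_per_residue: float = 1.51
    chain_phase_offsets: tuple[float, ...] = (0.0, 180.0)
    segments: tuple[SegmentOverride, ...] = ()

    def __post_init__(self) -> None:
        if self.n_residues < 7:
            raise ValueError("n_residues must be >= 7")
        if self.superhelix_radius <= 0 or self.helix_radius <= 0:
            raise ValueError("radii must be positive")
        if abs(self.superhelix_freq) >= self.helix_freq:
            raise ValueError("|superhelix_freq| must be < helix_freq")
        if len(self.chain_phase_offsets) != self.n_chains:
            raise ValueError("one chain_phase_offset per chain required")
        segs = sorted(self.segments, key=lambda s: s.start)
        last_end = 0
        for seg in segs:
            if not (1 <= seg.start <= seg.end <= self.n_residues):
                raise ValueError(
                    f"segment ({seg.start}, {seg.end}) outside [1, {self.n_residues}]"
                )
            if seg.start <= last_end:
                raise ValueError("segments overlap")
            if seg.superhelix_freq is not None:
                w1 = seg.helix_freq if seg.helix_freq is not None else self.helix_freq
                if abs(seg.superhelix_freq) >= w1:
                    raise ValueError("|superhelix_freq| must be < helix_freq in segment")
            last_end = seg.end

    # -- per-residue parameter tracks (the generator's exact ground truth) --

    def per_residue_freqs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (ω0, ω1, phase_jump) arrays of length ``n_residues``.

        Entry ``i`` (0-based) holds the parameters in effect for the angular
        step onto residue ``i + 1`` and the phase jump applied at residue
        ``i + 1`` (1-based numbering).
        """
        w0 = np.full(self.n_residues, self.superhelix_freq)
        w1 = np.full(self.n_residues, self.helix_freq)
        jump = np.zeros(self.n_residues)
        for seg in self.segments:
            sl = slice(seg.start - 1, seg.end)
            if seg.superhelix_freq is not None:
                w0[sl] = seg.superhelix_freq
            if seg.helix_freq is not None:
                w1[sl] = seg.helix_freq
            jump[seg.start - 1] += seg.phase_jump
        return w0, w1, jump

    def minor_phase(self) -> np.ndarray:
        """Minor-helix (Crick) phase of each residue, degrees, unwrapped."""
        _, w1, jump = self.per_residue_freqs()
        steps = np.concatenate(([0.0], w1[:-1]))
        return self.crick_phase + np.cumsum(steps) + np.cumsum(jump)

    def ground_truth_register(self) -> str:
        """Heptad position of each residue implied by the analytic phase."""
        bins = np.floor((self.minor_phase() % 360.0) / PHASE_BIN).astype(int) % 7
        return "".join(HEPTAD[(4 * b) % 7] for b in bins)


@dataclass
class Chain:
    """One helix of a bundle: ordered Cα coordinates plus residue identities."""

    residue_ids: np.ndarray
    residue_names: list[str]
    ca_coords: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.residue_ids) != len(self.ca_coords) or len(
            self.residue_names
        ) != len(self.residue_ids):
            raise ValueError("residue ids, names and coordinates must align")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class Bundle:
    """A multi-helix bundle (one folded model or trajectory frame)."""

    chains: list[Chain]
    parallel: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if len({len(c) for c in self.chains}) > 1:
            raise ValueError("all chains must have equal length")

    @property
    def n_residues(self) -> int:
        return len(self.chains[0])

    def coords(self) -> np.ndarray:
        """All Cα coordinates stacked chain-by-chain, shape (n_chains*n, 3)."""
        return np.vstack([c.ca_coords for c in self.chains])


@dataclass
class MeltCurve:
    """A thermal denaturation curve: CD signal versus temperature."""

    temperatures: np.ndarray
    signal: np.ndarray
    wavelength: float = 222.0
    units: str = "mdeg"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperatures) < 5:
            raise ValueError("melt curve needs at least 5 points")
        if len(self.temperatures) != len(self.signal):
            raise ValueError("temperatures and signal must align")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def generate_crick_bundle(
    params: CrickParams, sequence: str | None = None
) -> Bundle:
    """Build a Cα-only bundle that realizes ``params`` exactly.

    Each chain's local axis follows a helix of radius ``superhelix_radius``
    about the global z axis, advancing by the (piecewise) superhelical
    frequency per residue and rising by ``rise_per_residue`` along z.  The Cα
    is placed at ``helix_radius`` from the local axis at the minor-helix
    phase, measured from the direction toward the bundle axis, with positive
    phase advancing right-handedly about the local N→C axis direction.

    Parameters
    ----------
    params:
        Validated bundle description.
    sequence:
        One-letter amino-acid string of length ``n_residues``; poly-alanine
        when omitted.
    """
    n = params.n_residues
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise ValueError("sequence length must equal n_residues")

    w0_deg, _, _ = params.per_residue_freqs()
    w0 = np.deg2rad(w0_deg)
    theta1 = np.deg2rad(params.minor_phase())
    z = params.rise_per_residue * np.arange(n)
    r0, r1 = params.superhelix_radius, params.helix_radius

    chains = []
    for ci, offset in enumerate(params.chain_phase_offsets):
        steps = np.concatenate(([0.0], w0[:-1]))
        theta0 = np.deg2rad(offset) + np.cumsum(steps)
        axis = np.column_stack(
            [r0 * np.cos(theta0), r0 * np.sin(theta0), z]
        )
        # local tangent of the superhelical path (analytic derivative)
        tangent = np.column_stack(
            [
                -r0 * w0 * np.sin(theta0),
                r0 * w0 * np.cos(theta0),
                np.full(n, params.rise_per_residue),
            ]
        )
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        # unit vector toward the bundle axis, orthogonalized against the tangent
        inward = np.column_stack([-np.cos(theta0), -np.sin(theta0), np.zeros(n)])
        inward -= np.sum(inward * tangent, axis=1, keepdims=True) * tangent
        inward /= np.linalg.norm(inward, axis=1, keepdims=True)
        perp = np.cross(tangent, inward)
        ca = axis + r1 * (
            np.cos(theta1)[:, None] * inward + np.sin(theta1)[:, None] * perp
        )
        chains.append(
            Chain(
                residue_ids=np.arange(1, n + 1),
                residue_names=list(sequence),
                ca_coords=ca,
            )
        )
    return Bundle(chains=chains, parallel=True, provenance="crick-generator")


# ---------------------------------------------------------------------------
# Planted distortions
# ---------------------------------------------------------------------------

#: Default length (residues) of unwound / right-handed distortion segments.
DEFAULT_SEGMENT_LENGTH = 14

_DISTORTION_KINDS = ("stutter", "stammer", "unwound", "right_handed")


def inject_distortion(
    params: CrickParams,
    start: int,
    kind: str,
    length: int = DEFAULT_SEGMENT_LENGTH,
) -> CrickParams:
    """Return ``params`` with a named non-canonical event planted at ``start``.

    ``stutter`` and ``stammer`` are register discontinuities implemented as a
    single minor-helix phase jump between residues ``start − 1`` and
    ``start``: a stutter shifts the observed register so the transition
    advances 4 positions (phase −360/7°), a stammer so it advances 3
    positions (phase +4·360/7°).  ``unwound`` zeroes the superhelical
    frequency and ``right_handed`` flips its sign over ``length`` residues
    starting at ``start``.
    """
    if kind not in _DISTORTION_KINDS:
        raise ValueError(f"unknown distortion kind {kind!r}")
    if not (1 < start < params.n_residues):
        raise ValueError("start must be interior to the chain")
    if kind in ("stutter", "stammer"):
        jump = -PHASE_BIN if kind == "stutter" else 4.0 * PHASE_BIN
        seg = SegmentOverride(start=start, end=start, phase_jump=jump)
    else:
        end = min(start + length - 1, params.n_residues)
        w0 = 0.0 if kind == "unwound" else -params.superhelix_freq
        seg = SegmentOverride(start=start, end=end, superhelix_freq=w0)
    # CrickParams.__post_init__ re-validates, rejecting overlapping segments
    return replace(params, segments=params.segments + (seg,))


# ---------------------------------------------------------------------------
# Synthetic sequence families (probability tracks with planted architecture)
# ---------------------------------------------------------------------------


def generate_family(
    n: int,
    spec: Mapping[str, float] | None = None,
    length_range: tuple[int, int] = (320, 380),
    seed: int = 0,
):
    """Generate ``n`` coiled-coil probability tracks with planted labels.

    ``spec`` gives the planted fractions; keys (all optional):

    - ``has_hth``: fraction carrying an N-terminal helix-turn-helix interval
      (default 1.0).
    - ``cc_high``: fraction with a coiled-coil segment of probability ≥ 0.75
      (default 1.0).
    - ``cc_medium_only``: fraction whose best segment sits in [0.5, 0.75)
      (default 0.0).
    - ``cc_cterminal``: fraction whose high-confidence segment lies C-terminal
      to the HTH interval (default: equal to ``cc_high``).
    - ``noncanonical``: fraction *of CC-containing tracks* whose predicted
      register carries one planted heptad discontinuity (default 0.0).

    Realized counts are ``round(fraction · denominator)``, so the fractions
    are recovered exactly by downstream family summaries.  Deterministic for
    a fixed ``seed``.
    """
    from .family_architecture import CCTrack  # local import avoids a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    spec = dict(spec or {})
    known = {"has_hth", "cc_high", "cc_medium_only", "cc_cterminal", "noncanonical"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown fraction keys: {sorted(unknown)}")
    for key, val in spec.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"fraction {key} outside [0, 1]")
    f_hth = spec.get("has_hth", 1.0)
    f_high = spec.get("cc_high", 1.0)
    f_med = spec.get("cc_medium_only", 0.0)
    f_ct = spec.get("cc_cterminal", f_high)
    f_nc = spec.get("noncanonical", 0.0)
    if f_high + f_med > 1.0 + 1e-9:
        raise ValueError("cc_high + cc_medium_only exceeds 1")
    if f_ct > f_high + f_med + 1e-9:
        raise ValueError("cc_cterminal exceeds the CC-containing fraction")
    if f_ct > f_high + 1e-9:
        raise ValueError("cc_cterminal exceeds cc_high")

    rng = np.random.default_rng(seed)
    n_high = round(f_high * n)
    n_med = round(f_med * n)
    n_cc = n_high + n_med
    n_ct = round(f_ct * n)
    n_hth = round(f_hth * n)
    n_nc = round(f_nc * n_cc)

    order = rng.permutation(n)
    high_ids = set(order[:n_high])
    med_ids = set(order[n_high:n_cc])
    cc_ids = list(order[:n_cc])
    ct_ids = set(order[:n_ct])  # subset of high_ids by construction
    nc_ids = set(rng.choice(cc_ids, size=n_nc, replace=False)) if n_nc else set()
    # HTH assignment prefers tracks that need a C-terminal CC relationship
    hth_order = list(order[:n_ct]) + [i for i in order if i not in ct_ids]
    hth_ids = set(hth_order[:n_hth])

    tracks = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = rng.uniform(0.02, 0.30, size=length)
        heptad = ["-"] * length
        hth = [(5, 70)] if i in hth_ids else []
        labels = {
            "has_hth": i in hth_ids,
            "cc_high": i in high_ids,
            "cc_medium_only": i in med_ids,
            "cc_cterminal": i in ct_ids,
            "noncanonical": i in nc_ids,
            "cc_interval": None,
        }
        if i in high_ids or i in med_ids:
            if i in high_ids and i not in ct_ids:
                # plant the CC N-terminal and move the HTH to the C-terminus
                seg = (5, length - 90)
                if i in hth_ids:
                    hth = [(length - 75, length - 10)]
            else:
                seg = (81, length - 5)
            lo, hi = (0.85, 0.95) if i in high_ids else (0.55, 0.65)
            probs[seg[0] - 1 : seg[1]] = rng.uniform(lo, hi, size=seg[1] - seg[0] + 1)
            labels["cc_interval"] = seg
            for j in range(seg[0], seg[1] + 1):
                heptad[j - 1] = HEPTAD[(j - seg[0]) % 7]
            if i in nc_ids:
                # stutter-like break: register advances 4 positions at the seam
                mid = (seg[0] + seg[1]) // 2
                for j in range(mid, seg[1] + 1):
                    shifted = (j - seg[0] + 3) % 7
                    heptad[j - 1] = HEPTAD[shifted]
                labels["noncanonical_at"] = mid
        tracks.append(
            CCTrack(
                track_id=f"synth_{i:04d}",
                probs=probs,
                heptad=heptad,
                hth_intervals=hth,
                labels=labels,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------


def generate_melt_curve(
    tm: float,
    slope: float = 2.5,
    baselines: tuple[float, float] = (-20000.0, -2000.0),
    t_grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    units: str = "mre",
) -> MeltCurve:
    """Two-state sigmoid melting curve with additive Gaussian noise.

    signal(T) = folded + (unfolded − folded) · logistic((T − tm) / slope).

    ``t_grid`` defaults to 10–90 °C in 2 °C steps, the standard CD melting
    protocol.  ``slope`` is the transition width parameter in °C.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if t_grid is None:
        t_grid = np.arange(10.0, 91.0, 2.0)
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not (t[0] <= tm <= t[-1]):
        import warnings

        warnings.warn(
            "tm outside the temperature grid; downstream extraction will fail",
            stacklevel=2,
        )
    folded, unfolded = baselines
    frac = 1.0 / (1.0 + np.exp(-(t - tm) / slope))
    signal = folded + (unfolded - folded) * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=len(t))
    return MeltCurve(temperatures=t, signal=signal, units=units)


# ---------------------------------------------------------------------------
# Sequence assignment with controlled heptad-position composition
# ---------------------------------------------------------------------------


def assign_sequence(
    register: str | Iterable[str],
    composition: Mapping[str, Mapping[str, float]],
    seed: int = 0,
) -> str:
    """Draw an amino-acid sequence from per-heptad-position distributions.

    ``register`` is a string over ``a–g`` (``-`` allowed for unassigned
    residues, drawn from the pooled composition).  ``composition`` maps each
    heptad position to a distribution ``{one-letter aa: probability}``.
    Deterministic for a fixed seed.
    """
    reg = "".join(register)
    if len(reg) == 0:
        raise ValueError("empty register")
    missing = {p for p in set(reg) - {"-"} if p not in composition}
    if missing:
        raise ValueError(f"composition missing positions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    pooled: dict[str, float] = {}
    for dist in composition.values():
        for aa, p in dist.items():
            pooled[aa] = pooled.get(aa, 0.0) + p
    out = []
    for pos in reg:
        dist = composition[pos] if pos != "-" else pooled
        aas = sorted(dist)
        probs = np.array([dist[a] for a in aas], dtype=float)
        probs = probs / probs.sum()
        out.append(rng.choice(aas, p=probs))
    return "".join(out)
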