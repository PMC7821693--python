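"""Per-residue supercoiling maps over model ensembles and trajectories.

A map has one row per folded model (ranked by score, best on top) or per
trajectory frame (in time order), and one column per residue of the
coiled-coil domain.  Cell values are the chain-averaged local supercoil angle
in °/residue; cells without an estimate (chain termini) are missing.
Persistent non-canonical regions — runs of columns whose cells depart from
the canonical left-handed geometry in a sufficient fraction of rows — are
called from the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .bundle_geometry import DEAD_ZONE, measure_bundle
from .synthetic_bundles import Bundle

__all__ = [
    "SupercoilMap",
    "RegionCall",
    "ensemble_supercoil_map",
    "trajectory_map",
    "call_noncanonical_regions",
]


@dataclass
class SupercoilMap:
    """Rectangular matrix of local supercoil values (NaN = missing)."""

    values: np.ndarray  # (n_rows, n_cols)
    row_ids: list[str]
    columns: np.ndarray  # residue labels in domain numbering
    row_order: str = "by_score"  # or "by_time"
    row_meta: np.ndarray | None = None  # scores or times, aligned with rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = np.asarray(self.columns, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("row/column metadata does not match value shape")
        if self.row_order not in ("by_score", "by_time", "input"):
            raise ValueError(f"unknown row_order {self.row_order!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RegionCall:
    """A persistent non-canonical region of the coiled-coil domain."""

    interval: tuple[int, int]  # closed residue range, domain numbering
    persistence: float  # mean fraction of non-canonical rows inside
    location_label: str  # n_terminal | central | c_terminal

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence outside [0, 1]")


def _map_from_bundles(
    bundles: Sequence[Bundle],
    row_ids: list[str],
    domain_offset: int,
    dead_zone: float,
) -> tuple[np.ndarray, np.ndarray]:
    shapes = {(len(b.chains), b.n_residues) for b in bundles}
    if len(shapes) != 1:
        raise ValueError(f"topology mismatch across models: {sorted(shapes)}")
    n = bundles[0].n_residues
    values = np.full((len(bundles), n), np.nan)
    for r, bundle in enumerate(bundles):
        meas = measure_bundle(bundle, dead_zone=dead_zone, with_phases=False)
        values[r] = meas.supercoil.values
    columns = np.arange(1, n + 1) + domain_offset
    return values, columns


def ensemble_supercoil_map(
    models: Sequence[Bundle],
    scores: Sequence[float] | None = None,
    domain_offset: int = 0,
    dead_zone: float = DEAD_ZONE,
) -> SupercoilMap:
    """Measure every model and stack the supercoil traces into a map.

    Rows are sorted ascending by ``scores`` (best/lowest first) when given,
    else kept in input order.  ``domain_offset`` shifts column labels into
    domain numbering (offset 76 labels residue 1 as 77).
    """
    if not models:
        raise ValueError("no models given")
    if scores is not None and len(scores) != len(models):
        raise ValueError("one score per model required")
    values, columns = _map_from_bundles(
        models,
        [f"model_{i}" for i in range(len(models))],
        domain_offset,
        dead_zone,
    )
    row_ids = [f"model_{i}" for i in range(len(models))]
    meta = None
    if scores is not None:
        order = np.argsort(scores, kind="stable")
        values = values[order]
        row_ids = [row_ids[i] for i in order]
        meta = np.asarray(scores, dtype=float)[order]
    return SupercoilMap(
        values=values,
        row_ids=row_ids,
        columns=columns,
        row_order="by_score" if scores is not None else "input",
        row_meta=meta,
    )


def trajectory_map(
    frames: Sequence[Bundle],
    times: Sequence[float] | None = None,
    domain_offset: int = 0,
    dead_zone: float = DEAD_ZONE,
) -> SupercoilMap:
    """Like :func:`ensemble_supercoil_map` but rows are frames in time order."""
    if not frames:
        raise ValueError("no frames given")
    if times is None:
        times = np.arange(len(frames), dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(frames):
        raise ValueError("one time per frame required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    values, columns = _map_from_bundles(
        frames, [f"frame_{i}" for i in range(len(frames))], domain_offset, dead_zone
    )
    return SupercoilMap(
        values=values,
        row_ids=[f"frame_{i}" for i in range(len(frames))],
        columns=columns,
        row_order="by_time",
        row_meta=times,
    )


def _not_left(values: np.ndarray, dead_zone: float) -> np.ndarray:
    """Default cell rule: non-canonical iff handedness is not left."""
    return values > -dead_zone


def call_noncanonical_regions(
    map_: SupercoilMap,
    cell_rule: Callable[[np.ndarray, float], np.ndarray] | None = None,
    persistence_min: float = 0.5,
    min_len: int = 7,
    dead_zone: float = DEAD_ZONE,
) -> list[RegionCall]:
    """Call persistent non-canonical regions from a supercoil map.

    A cell is non-canonical per ``cell_rule`` (default: its handedness is not
    left, i.e. value > −dead_zone).  A column is flagged when the fraction of
    non-canonical cells among its non-missing cells is ≥ ``persistence_min``;
    maximal runs of at least ``min_len`` flagged columns become region calls.
    The location label is assigned by terciles of the full column range
    (midpoint in the first tercile → n_terminal, last → c_terminal, else
    central).
    """
    if map_.values.size == 0:
        raise ValueError("empty map")
    rule = cell_rule or _not_left
    noncanon = rule(map_.values, dead_zone)
    valid = np.isfinite(map_.values)
    noncanon = noncanon & valid
    n_valid = valid.sum(axis=0)
    count = noncanon.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, count / n_valid, 0.0)
    # count >= 1 makes the persistence_min = 0 boundary flag exactly the
    # columns with at least one non-canonical cell
    flagged = (frac >= persistence_min) & (count >= 1) & (n_valid > 0)

    calls: list[RegionCall] = []
    cols = map_.columns
    lo_col, hi_col = cols[0], cols[-1]
    span = hi_col - lo_col + 1
    i = 0
    while i < len(flagged):
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flagged) and flagged[j + 1]:
            j += 1
        if j - i + 1 >= min_len:
            mid = 0.5 * (cols[i] + cols[j])
            tercile = (mid - lo_col) / span
            label = (
                "n_terminal"
                if tercile < 1 / 3
                else ("c_terminal" if tercile >= 2 / 3 else "central")
            )
            calls.append(
                RegionCall(
                    interval=(int(cols[i]), int(cols[j])),
                    persistence=float(np.mean(frac[i : j + 1])),
                    location_label=label,
                )
            )
        i = j + 1
    return calls
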