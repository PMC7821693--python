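"""Readers and writers for the package's file interfaces.

Structures travel as multi-MODEL Cα-only PDB (one MODEL per folded model or
trajectory frame, chains A/B), read through biotite so mmCIF inputs work with
the same code path.  Tabular interfaces are TSV with documented columns:
probability tracks (id, residue, probability[, heptad]), HTH intervals
(id, start, end), melting curves (temperature_C, signal), supercoil maps
(row id + one column per residue label).  Sequences travel as FASTA.  Every
writer emits a ``#``-prefixed header recording the package version and the
generating parameters, and is byte-stable for identical inputs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .ensemble_maps import SupercoilMap
from .family_architecture import ArchitectureSummary, CCTrack
from .property_profiles import PropertyProfile
from .synthetic_bundles import Bundle, Chain, CrickParams, MeltCurve

__all__ = [
    "read_bundles",
    "write_bundles_pdb",
    "read_tracks",
    "write_tracks",
    "read_melt",
    "write_melt",
    "read_map",
    "write_map",
    "write_profile",
    "write_summary",
    "read_fasta",
    "write_fasta",
    "write_params_tsv",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def _header(kind: str, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# coilmap v{__version__} {kind}" + (f" {items}" if items else "") + "\n"


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def read_bundles(path: str | Path) -> list[Bundle]:
    """Read a multi-MODEL coordinate file into one Bundle per model.

    Accepts PDB or mmCIF (by extension).  Only Cα atoms are used; chain order
    and the file's 1-based residue numbering are preserved.  Errors on files
    without Cα atoms, with fewer than 2 chains, or with inconsistent chain
    lengths across models.
    """
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        f = pdbx.CIFFile.read(str(path))
        stack = pdbx.get_structure(f)
    else:
        f = pdb.PDBFile.read(str(path))
        stack = f.get_structure()
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms found")
    ca = stack[..., stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no Cα atoms found")
    chain_ids = list(dict.fromkeys(ca.chain_id))
    if len(chain_ids) < 2:
        raise ValueError(f"{path}: need Cα atoms for at least 2 chains")
    bundles = []
    lengths = None
    for m in range(stack.stack_depth()):
        model = ca[m]
        chains = []
        for cid in chain_ids:
            sel = model[model.chain_id == cid]
            names = [
                _THREE_TO_ONE.get(rn, "X") for rn in sel.res_name
            ]
            chains.append(
                Chain(
                    residue_ids=sel.res_id,
                    residue_names=names,
                    ca_coords=sel.coord,
                )
            )
        cur = tuple(len(c) for c in chains)
        if lengths is None:
            lengths = cur
        elif cur != lengths:
            raise ValueError(
                f"{path}: inconsistent chain lengths across models "
                f"(model 1: {lengths}, model {m + 1}: {cur})"
            )
        bundles.append(Bundle(chains=chains, provenance=str(path)))
    return bundles


def write_bundles_pdb(bundles: Sequence[Bundle], path: str | Path) -> None:
    """Write bundles as a multi-MODEL, Cα-only PDB file (chains A, B, …)."""
    if not bundles:
        raise ValueError("no bundles to write")
    first = bundles[0]
    n_atoms = sum(len(c) for c in first.chains)
    template = struc.AtomArray(n_atoms)
    idx = 0
    for ci, chain in enumerate(first.chains):
        cid = chr(ord("A") + ci)
        for ri in range(len(chain)):
            template.chain_id[idx] = cid
            template.res_id[idx] = chain.residue_ids[ri]
            template.res_name[idx] = _ONE_TO_THREE.get(chain.residue_names[ri], "ALA")
            template.atom_name[idx] = "CA"
            template.element[idx] = "C"
            template.hetero[idx] = False
            idx += 1
    coords = np.stack([b.coords() for b in bundles])
    stack = struc.from_template(template, coords)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_params_tsv(params: CrickParams, path: str | Path) -> None:
    """Sidecar TSV with the generator's exact ground-truth parameters."""
    with open(path, "w") as fh:
        fh.write(_header("crick-params"))
        fh.write("field\tvalue\n")
        for name in (
            "n_residues", "n_chains", "superhelix_radius", "helix_radius",
            "superhelix_freq", "helix_freq", "crick_phase", "rise_per_residue",
        ):
            fh.write(f"{name}\t{getattr(params, name)}\n")
        fh.write(f"chain_phase_offsets\t{','.join(map(str, params.chain_phase_offsets))}\n")
        for seg in params.segments:
            fh.write(
                "segment\t"
                f"{seg.start}:{seg.end}:w0={seg.superhelix_freq}:"
                f"w1={seg.helix_freq}:jump={seg.phase_jump}\n"
            )


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_tracks(
    path: str | Path, hth_path: str | Path | None = None
) -> list[CCTrack]:
    """Read probability tracks (columns: id, residue, probability[, heptad]).

    ``hth_path``, if given, supplies HTH intervals (columns: id, start, end).
    Residues must be 1-based and contiguous per id; probabilities are
    validated to [0, 1] with line-numbered error messages.
    """
    df = _read_tsv(path, ("id", "residue", "probability"))
    bad = df[(df["probability"] < 0) | (df["probability"] > 1)]
    if len(bad):
        line = int(bad.index[0]) + 2  # 1-based, after the header line
        raise ValueError(f"{path}: probability outside [0, 1] at line {line}")
    hth: dict[str, list[tuple[int, int]]] = {}
    if hth_path is not None:
        hdf = _read_tsv(hth_path, ("id", "start", "end"))
        for _, row in hdf.iterrows():
            hth.setdefault(str(row["id"]), []).append(
                (int(row["start"]), int(row["end"]))
            )
    tracks = []
    for tid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("residue")
        res = grp["residue"].to_numpy()
        if res[0] != 1 or np.any(np.diff(res) != 1):
            raise ValueError(f"{path}: track {tid!r} residues not contiguous from 1")
        heptad = None
        if "heptad" in grp.columns:
            heptad = [str(h) if str(h) in "abcdefg" else "-" for h in grp["heptad"]]
        tracks.append(
            CCTrack(
                track_id=str(tid),
                probs=grp["probability"].to_numpy(),
                heptad=heptad,
                hth_intervals=hth.get(str(tid), []),
            )
        )
    return tracks


def write_tracks(tracks: Sequence[CCTrack], path: str | Path,
                 hth_path: str | Path | None = None) -> None:
    """Write tracks (and optionally their HTH intervals) as TSV."""
    with open(path, "w") as fh:
        fh.write(_header("cc-tracks", n=len(tracks)))
        fh.write("id\tresidue\tprobability\theptad\n")
        for tr in tracks:
            heptad = tr.heptad or ["-"] * tr.length
            for i in range(tr.length):
                fh.write(f"{tr.track_id}\t{i + 1}\t{tr.probs[i]:.4f}\t{heptad[i]}\n")
    if hth_path is not None:
        with open(hth_path, "w") as fh:
            fh.write(_header("hth-intervals"))
            fh.write("id\tstart\tend\n")
            for tr in tracks:
                for lo, hi in tr.hth_intervals:
                    fh.write(f"{tr.track_id}\t{lo}\t{hi}\n")


def read_melt(path: str | Path) -> MeltCurve:
    """Read a melting curve (columns: temperature_C, signal)."""
    df = _read_tsv(path, ("temperature_C", "signal"))
    return MeltCurve(
        temperatures=df["temperature_C"].to_numpy(),
        signal=df["signal"].to_numpy(),
    )


def write_melt(curve: MeltCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("melt-curve", wavelength=curve.wavelength, units=curve.units))
        fh.write("temperature_C\tsignal\n")
        for t, s in zip(curve.temperatures, curve.signal):
            fh.write(f"{t:.6g}\t{s:.6g}\n")


def write_map(map_: SupercoilMap, path: str | Path) -> None:
    """Write a supercoil map as TSV (header row of residue labels)."""
    with open(path, "w") as fh:
        fh.write(_header("supercoil-map", row_order=map_.row_order))
        fh.write("row\t" + "\t".join(map(str, map_.columns)) + "\n")
        for rid, row in zip(map_.row_ids, map_.values):
            cells = "\t".join("" if not np.isfinite(v) else f"{v:.6f}" for v in row)
            fh.write(f"{rid}\t{cells}\n")


def read_map(path: str | Path) -> SupercoilMap:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return SupercoilMap(
        values=df.to_numpy(dtype=float),
        row_ids=[str(i) for i in df.index],
        columns=np.array([int(c) for c in df.columns]),
        row_order="input",
    )


def write_profile(profile: PropertyProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            _header(
                "property-profile",
                hydrophobicity=profile.hydrophobicity_scale,
                volume=profile.volume_scale,
            )
        )
        fh.write("position\tcount\thydrophobicity\tvolume\n")
        frame = profile.as_frame()
        for pos, row in frame.iterrows():
            fh.write(
                f"{pos}\t{int(row['count'])}\t{row['hydrophobicity']:.6g}\t"
                f"{row['volume']:.6g}\n"
            )


def write_summary(summary: ArchitectureSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("family-summary"))
        fh.write("metric\tvalue\n")
        fh.write(f"n_sequences\t{summary.n_sequences}\n")
        fh.write(f"frac_cc_medium\t{summary.frac_cc_medium:.6g}\n")
        fh.write(f"frac_cc_high\t{summary.frac_cc_high:.6g}\n")
        fh.write(f"frac_cc_cterminal\t{summary.frac_cc_cterminal:.6g}\n")
        fh.write(f"frac_noncanonical\t{summary.frac_noncanonical:.6g}\n")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
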