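"""Readers and writers shared by the analysis stages.

Text formats only: long-format uptake CSV (a documented subset of a
DynamX-style state export), progress-curve CSV, multi-frame XYZ and
multi-model PDB trajectories, and YAML group definitions.  HDX residue
coordinates are 1-based inclusive (community convention); trajectory
particle indices are 0-based (API convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .hdx import PeptideUptake
from .trajectory import Trajectory

__all__ = [
    "read_uptake_csv",
    "write_uptake_csv",
    "read_trajectory",
    "write_xyz",
    "read_progress_csv",
    "write_progress_csv",
    "write_provenance",
]

UPTAKE_COLUMNS = ["protein", "sequence", "start", "end", "state",
                  "exposure_min", "replicate", "uptake_Da"]


class ParseError(ValueError):
    """Malformed input file; message names the offending row or frame."""


def read_uptake_csv(path) -> List[PeptideUptake]:
    """Read a long-format peptide uptake table into PeptideUptake records.

    Required columns: protein, sequence, start, end, state, exposure_min,
    replicate, uptake_Da; optional fd_uptake_Da.  Rows are grouped by
    (sequence, span, state, exposure); span/sequence consistency is enforced
    per row.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for i, row in df.iterrows():
        if int(row["end"]) - int(row["start"]) + 1 != len(str(row["sequence"])):
            raise ParseError(
                f"{path} row {i + 2}: span {row['start']}-{row['end']} inconsistent "
                f"with sequence {row['sequence']!r}")
    records = []
    keys = ["sequence", "start", "end", "state", "exposure_min"]
    for (seq, start, end, state, expo), grp in df.groupby(keys, sort=True):
        fd = None
        if "fd_uptake_Da" in grp.columns and grp["fd_uptake_Da"].notna().any():
            fd = float(grp["fd_uptake_Da"].dropna().iloc[0])
        records.append(PeptideUptake(
            sequence=str(seq), span=(int(start), int(end)), state=str(state),
            exposure=float(expo),
            replicates=grp.sort_values("replicate")["uptake_Da"].astype(float).tolist(),
            fd_uptake=fd))
    return records


def write_uptake_csv(records: Sequence[PeptideUptake], path,
                     protein: str = "construct", header_comment: str = "") -> None:
    rows = []
    for r in records:
        for k, d in enumerate(r.replicates, start=1):
            rows.append({
                "protein": protein, "sequence": r.sequence,
                "start": r.span[0], "end": r.span[1], "state": r.state,
                "exposure_min": r.exposure, "replicate": k, "uptake_Da": d,
                "fd_uptake_Da": r.fd_uptake if r.fd_uptake is not None else np.nan,
            })
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_progress_csv(path) -> Dict[float, Tuple[np.ndarray, np.ndarray]]:
    """Progress curves as {conc_nM: (time_min, product_uM)}."""
    df = pd.read_csv(path, comment="#")
    need = {"time_min", "conc_nM", "product_uM"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    out = {}
    for conc, grp in df.groupby("conc_nM"):
        grp = grp.sort_values("time_min")
        out[float(conc)] = (grp["time_min"].to_numpy(float),
                            grp["product_uM"].to_numpy(float))
    return out


def write_progress_csv(curves: Dict[float, Tuple[np.ndarray, np.ndarray]], path,
                       header_comment: str = "") -> None:
    rows = []
    for conc, (t, p) in sorted(curves.items()):
        for ti, pi in zip(t, p):
            rows.append({"time_min": ti, "conc_nM": conc, "product_uM": pi})
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_xyz(traj: Trajectory, path, header_comment: str = "") -> None:
    """Write a multi-frame XYZ file; the comment line carries provenance.

    Group definitions are embedded in the first frame's comment as JSON so
    that a round trip preserves them.
    """
    meta = {"groups": {k: v.tolist() for k, v in traj.groups.items()},
            "units": traj.units}
    labels = list(traj.labels) if traj.labels is not None else \
        [f"X{i}" for i in range(traj.n_particles)]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            if f == 0:
                fh.write(f"allokin {header_comment} meta={json.dumps(meta)}\n")
            else:
                fh.write(f"frame {f}\n")
            for lbl, (x, y, z) in zip(labels, traj.coordinates[f]):
                fh.write(f"{lbl} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz(path) -> Trajectory:
    frames, labels, groups, units = [], None, {}, "nm"
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if frame_idx == 0 and "meta=" in comment:
            meta = json.loads(comment.split("meta=", 1)[1])
            groups = {k: np.asarray(v, int) for k, v in meta.get("groups", {}).items()}
            units = meta.get("units", "nm")
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame {frame_idx}")
        xyz, lbl = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed atom line in frame {frame_idx}")
            lbl.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if labels is None:
            labels = lbl
        elif len(lbl) != len(labels):
            raise ParseError(f"{path}: frame {frame_idx} has {len(lbl)} particles, "
                             f"expected {len(labels)}")
        frames.append(xyz)
        i += 2 + n
        frame_idx += 1
    if len(frames) < 2:
        raise ParseError(f"{path}: need at least 2 frames, found {len(frames)}")
    return Trajectory(np.asarray(frames), labels=labels, groups=groups, units=units)


def _read_pdb_models(path) -> Trajectory:
    import warnings

    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = [u.atoms.positions.copy() for _ in u.trajectory]
        labels = [a.name for a in u.atoms]
    if len(frames) < 2:
        raise ParseError(f"{path}: need at least 2 MODEL records")
    sizes = {f.shape[0] for f in frames}
    if len(sizes) != 1:
        raise ParseError(f"{path}: particle count differs across models")
    return Trajectory(np.asarray(frames, float), labels=labels, units="angstrom")


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB trajectory."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb_models(path)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def read_groups_yaml(path, n_particles: int) -> Dict[str, np.ndarray]:
    """Group definitions: name -> explicit index list or [start, stop] range."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = {}
    for name, spec in raw.items():
        if isinstance(spec, dict) and "range" in spec:
            lo, hi = spec["range"]
            idx = np.arange(lo, hi + 1)
        else:
            idx = np.asarray(spec, int)
        if idx.min() < 0 or idx.max() >= n_particles:
            raise ParseError(f"group {name!r}: indices out of range 0..{n_particles - 1}")
        groups[name] = idx
    return groups


def write_provenance(out_dir, config: dict, seed: int | None = None) -> Path:
    """Write a provenance record (config + package version + seed) for a run."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {"package": "allokin", "version": __version__,
           "seed": seed, "config": config}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(rec, indent=2, default=str) + "\n")
    return path
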