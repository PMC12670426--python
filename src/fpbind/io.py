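"""File formats: plate CSVs, XYZ trajectories, dihedral tables, results.

The plate CSV dialect is strict: UTF-8, comma-separated, dot decimal, with
mandatory columns ``compound, target, mode, concentration_M, anisotropy,
replicate, experiment``.  Unknown columns are preserved on the parsed
tables but ignored by the fitters.  Rows whose numeric fields do not parse
are reported with their file line numbers and skipped; a numeric column
with no parseable values at all (the signature of a comma-decimal export)
is a schema error.

XYZ trajectories are read and written through MDAnalysis (standard XYZ
dialect: atom-count line, comment line, ``element x y z`` in Å).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .fitting import TitrationCurve
from .pose import DihedralDataset

logger = logging.getLogger("fpbind")

PLATE_COLUMNS = (
    "compound", "target", "mode", "concentration_M", "anisotropy",
    "replicate", "experiment",
)

__all__ = [
    "PLATE_COLUMNS",
    "parse_plate_csv",
    "write_plate_csv",
    "read_xyz",
    "write_xyz",
    "read_dihedral_csv",
    "write_dihedral_csv",
    "write_results",
]


def parse_plate_csv(path, probe_total=None, protein_total=None):
    """Parse a plate CSV into one :class:`TitrationCurve` per (compound, target).

    ``probe_total``/``protein_total`` (M) are assay constants not stored in
    the plate file; they are attached to every parsed curve.  Returns a dict
    keyed by ``(compound, target)``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:
        raise SchemaError(f"could not read plate CSV {path}: {exc}") from exc
    missing = [c for c in PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"plate CSV {path} is missing mandatory columns: {missing}",
            missing_columns=missing,
        )

    for col in ("concentration_M", "anisotropy"):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if numeric.notna().sum() == 0:
            raise SchemaError(
                f"column {col!r} in {path} has no parseable numbers; the dialect "
                "requires dot-decimal values"
            )
        if bad.any():
            # +2: one for the header line, one for 0-based indexing.
            lines = [int(i) + 2 for i in raw.index[bad]]
            logger.warning("%s: skipping %d unparseable rows (lines %s)",
                           path, len(lines), lines)
        raw[col] = numeric
    raw = raw.dropna(subset=["concentration_M", "anisotropy"]).reset_index(drop=True)

    curves = {}
    for (compound, target, mode), group in raw.groupby(
        ["compound", "target", "mode"], sort=False
    ):
        curves[(compound, target)] = TitrationCurve(
            data=group.reset_index(drop=True),
            mode=mode,
            probe_total=probe_total,
            protein_total=protein_total,
            compound=compound,
            target=target,
        )
    return curves


def write_plate_csv(curves, path):
    """Write curves (iterable of TitrationCurve) to the plate CSV dialect."""
    parts = []
    for curve in curves:
        part = curve.data.copy()
        part.insert(0, "compound", curve.compound)
        part.insert(1, "target", curve.target)
        part.insert(2, "mode", curve.mode)
        parts.append(part[list(PLATE_COLUMNS)])
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def _require_mdanalysis():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_xyz(path):
    """Read a (multi-frame) XYZ file: returns (coords, labels).

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``labels`` are the
    element/name strings of the first column.
    """
    mda = _require_mdanalysis()
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"XYZ file {path} is missing or empty")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path))
            labels = [str(n) for n in universe.atoms.names]
            coords = np.array(
                [universe.atoms.positions.copy() for _ in universe.trajectory],
                dtype=float,
            )
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"could not parse XYZ file {path}: {exc}") from exc
    return coords, labels


def write_xyz(path, coords, labels=None):
    """Write coordinates (n_frames, n_atoms, 3) or (n_atoms, 3) as XYZ."""
    mda = _require_mdanalysis()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n_atoms = coords.shape[1]
    labels = labels or ["C"] * n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(n_atoms, trajectory=True)
        universe.add_TopologyAttr("names", [str(x) for x in labels])
        universe.add_TopologyAttr("elements", [str(x).rstrip("0123456789") or "C"
                                               for x in labels])
        with mda.Writer(str(path), n_atoms) as writer:
            for frame in coords:
                universe.atoms.positions = frame
                writer.write(universe.atoms)


def read_dihedral_csv(path) -> DihedralDataset:
    """Read a dihedral table CSV (ligand_id, frame, phi1..phiK in degrees)."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"could not read dihedral CSV {path}: {exc}") from exc
    return DihedralDataset(data=table)


def write_dihedral_csv(dataset: DihedralDataset, path):
    dataset.data.to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(document: dict, path):
    """Write a result document as deterministic, sorted-key JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(document, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
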