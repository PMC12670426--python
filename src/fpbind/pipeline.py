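"""End-to-end orchestration: plate CSV in, Kd/selectivity tables out.

``run_affinity_pipeline`` reproduces the reporting shape of a competitive
FP SAR campaign: per compound-target pair a mean ± SD Kd across
independent experiments, plus a fold-selectivity table Kd(off-target) /
Kd(target) for compounds measured against both galectins.

``run_pose_pipeline`` reproduces the trajectory post-analysis: per-frame
ligand RMSD to a reference pose, bound-frame counts on the full series and
on an equally spaced visualization subsample, and a pooled dPCA embedding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .fitting import fit_competitive, fit_direct, fold_selectivity
from .io import (
    parse_plate_csv,
    read_dihedral_csv,
    read_xyz,
    write_results,
)
from .pose import (
    DihedralPCA,
    PoseTrajectory,
    count_bound_frames,
    rmsd_to_reference,
    subsample_equally_spaced,
)

logger = logging.getLogger("fpbind")

_UNIT_SCALE = {"M": 1.0, "uM": 1e6, "nM": 1e9}

__all__ = ["RunConfig", "run_affinity_pipeline", "run_pose_pipeline"]


def _package_version():
    try:
        return version("fpbind")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Flat configuration for pipeline runs.

    Assay constants default to the package's synthetic-assay conventions
    (probe Kd* 50 nM, protein at twice Kd*, probe 20 nM); real campaigns
    override them with the measured values.  Round-trips losslessly through
    its YAML flat-mapping file form.
    """

    plate_csv: str | None = None
    trajectory_xyz: str | None = None
    reference_xyz: str | None = None
    dihedral_csv: str | None = None
    ligand_id: str = "ligand"
    probe_kd: float = 50e-9
    protein_total: float = 100e-9
    probe_total: float = 20e-9
    rmsd_threshold: float = 2.0
    n_visual: int = 30
    n_dpca: int = 10000
    seed: int = 0
    out_dir: str = "results"
    units: str = "uM"
    selectivity_off_target: str = "Gal-1"
    selectivity_target: str = "Gal-3C"

    def __post_init__(self):
        if self.units not in _UNIT_SCALE:
            raise ValidationError(f"units must be one of {sorted(_UNIT_SCALE)}")
        for name in ("probe_kd", "protein_total", "probe_total", "rmsd_threshold"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("plate_csv", "trajectory_xyz", "reference_xyz", "dihedral_csv"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{name} file does not exist: {path}")

    @classmethod
    def from_file(cls, path):
        with open(path, encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ValidationError(f"config file {path} must be a flat key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_file(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self):
        """Stable hash of the configuration, recorded in run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log_run(config, what):
    logger.info("fpbind %s | %s | seed=%s | config=%s",
                _package_version(), what, config.seed, config.digest())


def run_affinity_pipeline(config: RunConfig) -> dict:
    """Fit every curve in the plate CSV and assemble the reporting tables.

    Direct-mode curves refine the probe Kd* first; competitive-mode curves
    are then fitted per experiment against that Kd* and aggregated.  Writes
    ``affinity_results.json`` and ``fitted_curves.csv`` under
    ``config.out_dir`` and returns the result document.
    """
    if config.plate_csv is None:
        raise ValidationError("config.plate_csv is required for the affinity pipeline")
    _log_run(config, "affinity pipeline")
    curves = parse_plate_csv(config.plate_csv, probe_total=config.probe_total,
                             protein_total=config.protein_total)
    scale = _UNIT_SCALE[config.units]

    probe_kd = config.probe_kd
    direct_fits = {}
    for key, curve in curves.items():
        if curve.mode == "direct":
            res = fit_direct(curve)
            direct_fits[key] = res
            probe_kd = res.probe_kd
            logger.info("direct fit %s: Kd* = %.4g M", key, res.probe_kd)

    compounds = {}
    curve_rows = []
    for (compound, target), curve in curves.items():
        if curve.mode != "competitive":
            continue
        result = fit_competitive(curve, probe_kd=probe_kd)
        entry = {
            "compound": compound,
            "target": target,
            "kd_mean": result.kd_mean * scale,
            "kd_sd": result.kd_sd * scale if result.sd_defined else None,
            "kd_per_experiment": [k * scale for k in result.kd_per_experiment],
            "units": config.units,
            "n_experiments": len(result.kd_per_experiment),
            "sd_defined": result.sd_defined,
            "weak_binder": result.weak_binder,
            "converged": result.converged,
            "experiments": [
                {"experiment": str(e.experiment_id), "kd": e.kd * scale,
                 "r_free": e.r_free, "r_bound": e.r_bound, "rss": e.rss,
                 "weak_binder": e.weak_binder}
                for e in result.experiments
            ],
        }
        compounds.setdefault(compound, {})[target] = entry
        conc = curve.data["concentration_M"].to_numpy(dtype=float)
        positive = conc[conc > 0]
        grid = np.geomspace(positive.min(), positive.max(), 60)
        curve_rows.append(pd.DataFrame({
            "compound": compound, "target": target,
            "concentration_M": grid, "anisotropy": result.predict(grid),
        }))

    selectivity = {}
    for compound, per_target in compounds.items():
        off = per_target.get(config.selectivity_off_target)
        tgt = per_target.get(config.selectivity_target)
        if off is None or tgt is None:
            logger.warning("selectivity omitted for %s: need both %s and %s",
                           compound, config.selectivity_off_target,
                           config.selectivity_target)
            continue
        selectivity[compound] = {
            "fold_selectivity": fold_selectivity(off["kd_mean"], tgt["kd_mean"]),
            "fold_selectivity_2sf": fold_selectivity(off["kd_mean"], tgt["kd_mean"],
                                                     sig_figs=2),
        }

    document = {
        "package_version": _package_version(),
        "seed": config.seed,
        "config_digest": config.digest(),
        "probe_kd_M": probe_kd,
        "units": config.units,
        "compounds": compounds,
        "selectivity": selectivity,
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results(document, out_dir / "affinity_results.json")
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out_dir / "fitted_curves.csv", index=False
        )
    return document


def run_pose_pipeline(config: RunConfig) -> dict:
    """RMSD, bound-frame and dPCA statistics for one ligand trajectory.

    The dPCA is fitted on the pooled dihedrals of every ligand present in
    the dihedral CSV (equally spaced subsample of up to ``config.n_dpca``
    frames per ligand) and applied per ligand.  Writes
    ``pose_results.json`` and ``dpca_embedding.csv``.
    """
    if config.trajectory_xyz is None or config.reference_xyz is None:
        raise ValidationError(
            "config.trajectory_xyz and config.reference_xyz are required"
        )
    _log_run(config, "pose pipeline")
    frames, labels = read_xyz(config.trajectory_xyz)
    reference, _ = read_xyz(config.reference_xyz)
    traj = PoseTrajectory(frames=frames, reference=reference[0], atom_labels=labels)

    rmsd = rmsd_to_reference(traj)
    full = count_bound_frames(rmsd, config.rmsd_threshold)
    n_vis = min(config.n_visual, traj.n_frames)
    vis_idx = subsample_equally_spaced(traj.n_frames, n_vis)
    vis = count_bound_frames(rmsd[vis_idx], config.rmsd_threshold)

    document = {
        "package_version": _package_version(),
        "seed": config.seed,
        "config_digest": config.digest(),
        "ligand_id": config.ligand_id,
        "n_frames": traj.n_frames,
        "rmsd_threshold_A": config.rmsd_threshold,
        "bound_fraction_full": full.fraction,
        "bound_count_full": full.count,
        "visual_subsample": {"n": n_vis, "bound_count": vis.count,
                             "bound_fraction": vis.fraction},
    }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.dihedral_csv is not None:
        dataset = read_dihedral_csv(config.dihedral_csv)
        pooled = []
        for ligand in dataset.ligand_ids:
            angles = dataset.angles(ligand)
            take = subsample_equally_spaced(
                angles.shape[0], min(config.n_dpca, angles.shape[0])
            )
            pooled.append(angles[take])
        model = DihedralPCA(n_components=2).fit(np.vstack(pooled))
        embedding_rows = []
        for ligand in dataset.ligand_ids:
            sub = dataset.data[dataset.data["ligand_id"] == ligand]
            scores = model.transform(sub[dataset.angle_columns].to_numpy(float))
            part = pd.DataFrame({
                "ligand_id": ligand,
                "frame": sub["frame"].to_numpy(),
                "dPC1": scores[:, 0],
                "dPC2": scores[:, 1],
            })
            if ligand == config.ligand_id and len(part) == traj.n_frames:
                part["rmsd"] = rmsd
                part["bound_flag"] = rmsd < config.rmsd_threshold
            else:
                part["rmsd"] = np.nan
                part["bound_flag"] = pd.NA
            embedding_rows.append(part)
        pd.concat(embedding_rows, ignore_index=True).to_csv(
            out_dir / "dpca_embedding.csv", index=False
        )
        document["dpca"] = {
            "n_ligands": len(dataset.ligand_ids),
            "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
        }

    write_results(document, out_dir / "pose_results.json")
    return document
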