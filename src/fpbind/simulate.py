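"""Seeded generators for synthetic assay and trajectory data.

The generators emulate the structure of a competitive-FP SAR campaign and
its MD post-analysis:

* serial-dilution titration plates (geometric dilution series, a small
  number of independent experiments each measured in triplicate, i.i.d.
  Gaussian noise on anisotropy),
* two-state (bound/unbound) ligand trajectories with matched dihedral
  time series, standing in for ordered vs disordered binding behaviour.

Everything is bit-reproducible given (seed, design).  Noise streams are
derived per (experiment, replicate) with a CRC32-based sub-seed, so adding
replicates or experiments never perturbs the ones already generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import (
    AnisotropyModel,
    EquilibriumSystem,
    _competitive_fb_arrays,
    anisotropy_from_fraction,
    direct_fraction_bound,
)
from .errors import ValidationError
from .fitting import TitrationCurve
from .pose import DihedralDataset, PoseTrajectory

__all__ = [
    "PlateDesign",
    "TwoStateTrajectoryDesign",
    "simulate_direct_titration",
    "simulate_competition_plate",
    "simulate_pose_trajectory",
]


@dataclass(frozen=True)
class PlateDesign:
    """Serial-dilution plate layout and noise level.

    Defaults follow the assay convention the analysis targets: a 10-point
    3-fold dilution from 100 µM (bracketing µM-to-nM affinities), three
    independent experiments each in triplicate, and instrument-like
    Gaussian noise of 0.002 anisotropy units.
    """

    dilution_factor: float = 3.0
    n_concentrations: int = 10
    top_concentration: float = 100e-6
    n_experiments: int = 3
    n_replicates: int = 3
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if not self.dilution_factor > 1:
            raise ValidationError("dilution_factor must be > 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if min(self.n_concentrations, self.n_experiments, self.n_replicates) < 1:
            raise ValidationError("all counts must be >= 1")
        if not self.top_concentration > 0:
            raise ValidationError("top_concentration must be > 0")

    def concentrations(self) -> np.ndarray:
        """Exact geometric dilution series, highest first (M)."""
        return self.top_concentration / self.dilution_factor ** np.arange(
            self.n_concentrations, dtype=float
        )


def _substream(seed, experiment_id, replicate_id) -> np.random.Generator:
    """Decoupled noise stream for one (experiment, replicate) well series."""
    tag = zlib.crc32(f"{experiment_id}|{replicate_id}".encode())
    return np.random.default_rng((int(seed) ^ tag) & 0x7FFFFFFF)


def _simulate_plate(design, conc, clean_signal, mode, probe_total, protein_total,
                    compound, target) -> TitrationCurve:
    rows = []
    for e in range(1, design.n_experiments + 1):
        exp_id = f"exp{e}"
        for r in range(1, design.n_replicates + 1):
            rep_id = f"rep{r}"
            rng = _substream(design.seed, exp_id, rep_id)
            noise = rng.normal(0.0, design.noise_sd, conc.size) if design.noise_sd else 0.0
            rows.append(pd.DataFrame({
                "concentration_M": conc,
                "anisotropy": clean_signal + noise,
                "replicate": rep_id,
                "experiment": exp_id,
            }))
    data = pd.concat(rows, ignore_index=True)
    return TitrationCurve(data=data, mode=mode, probe_total=probe_total,
                          protein_total=protein_total, compound=compound, target=target)


def simulate_direct_titration(design: PlateDesign, true_probe_kd, probe_total,
                              anis: AnisotropyModel | None = None,
                              compound="probe", target="") -> TitrationCurve:
    """Protein-into-probe titration on the exact quadratic model plus noise."""
    if not true_probe_kd > 0:
        raise ValidationError("true_probe_kd must be > 0")
    anis = anis or AnisotropyModel()
    conc = design.concentrations()
    fb = direct_fraction_bound(conc, probe_total, true_probe_kd)
    clean = anisotropy_from_fraction(fb, anis)
    return _simulate_plate(design, conc, clean, "direct", probe_total, None,
                           compound, target)


def simulate_competition_plate(design: PlateDesign, system: EquilibriumSystem,
                               anis: AnisotropyModel | None = None,
                               compound="", target="") -> TitrationCurve:
    """Inhibitor displacement curve on the exact ternary model plus noise.

    ``system.inhibitor_kd`` is the ground-truth Kd; ``inhibitor_total`` in
    the system is ignored — the dilution series comes from the design.
    """
    anis = anis or AnisotropyModel()
    conc = design.concentrations()
    if np.isfinite(system.inhibitor_kd):
        fb = _competitive_fb_arrays(system.protein_total, system.probe_total, conc,
                                    system.probe_kd, system.inhibitor_kd)
    else:  # non-binding competitor: flat curve at the no-inhibitor level
        fb = np.full_like(conc, direct_fraction_bound(
            system.protein_total, system.probe_total, system.probe_kd))
    fb = np.clip(fb, 0.0, 1.0)
    clean = anisotropy_from_fraction(fb, anis)
    return _simulate_plate(design, conc, clean, "competitive", system.probe_total,
                           system.protein_total, compound, target)


@dataclass(frozen=True)
class TwoStateTrajectoryDesign:
    """Hidden two-state (bound/unbound) trajectory generator settings.

    Each frame is bound with probability ``bound_occupancy``.  Bound frames
    sit on the reference pose up to isotropic atomic jitter; unbound frames
    are additionally displaced rigidly so their expected RMSD is
    ``unbound_rmsd_mean``.  Dihedrals are drawn from state-specific von
    Mises clusters (circular Gaussians) with concentration ``kappa``.
    """

    bound_occupancy: float = 0.9
    bound_rmsd_mean: float = 0.8
    unbound_rmsd_mean: float = 5.0
    jitter_sd: float = 0.3
    bound_dihedral_means: tuple = (-60.0, 60.0, 180.0, 0.0)
    unbound_dihedral_means: tuple = (60.0, 180.0, -60.0, 120.0)
    kappa: float = 50.0
    n_frames: int = 3000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bound_occupancy <= 1.0:
            raise ValidationError("bound_occupancy must lie in [0, 1]")
        if not (0.0 <= self.bound_rmsd_mean < self.unbound_rmsd_mean):
            raise ValidationError("need 0 <= bound_rmsd_mean < unbound_rmsd_mean")
        if self.jitter_sd < 0 or self.kappa <= 0 or self.n_frames < 1:
            raise ValidationError("invalid jitter_sd, kappa, or n_frames")
        if len(self.bound_dihedral_means) != len(self.unbound_dihedral_means):
            raise ValidationError("dihedral mean tuples must have equal length")


def _wrap_degrees(angles):
    """Wrap to (-180, 180]."""
    wrapped = np.mod(-np.asarray(angles, float) + 180.0, 360.0)
    return -(wrapped - 180.0)


def simulate_pose_trajectory(design: TwoStateTrajectoryDesign, n_atoms=20,
                             ligand_id="ligand"):
    """Two-state ligand trajectory with matched dihedral series.

    Returns ``(PoseTrajectory, DihedralDataset)``.  Expected RMSDs: bound
    frames ≈ bound_rmsd_mean (rigid offset + atomic jitter combined in
    quadrature), unbound frames ≈ unbound_rmsd_mean.
    """
    if n_atoms < 1:
        raise ValidationError("n_atoms must be >= 1")
    rng = np.random.default_rng(design.seed)
    reference = rng.normal(scale=2.0, size=(n_atoms, 3))
    bound = rng.random(design.n_frames) < design.bound_occupancy

    jitter = rng.normal(scale=design.jitter_sd / np.sqrt(3.0),
                        size=(design.n_frames, n_atoms, 3))

    def _rigid_offsets(target_rmsd, n):
        # Rigid displacement length so that offset^2 + jitter^2 = target^2.
        length = np.sqrt(max(target_rmsd**2 - design.jitter_sd**2, 0.0))
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        return length * direction

    offsets = np.zeros((design.n_frames, 3))
    offsets[bound] = _rigid_offsets(design.bound_rmsd_mean, int(bound.sum()))
    offsets[~bound] = _rigid_offsets(design.unbound_rmsd_mean, int((~bound).sum()))
    frames = reference[None, :, :] + offsets[:, None, :] + jitter

    n_dih = len(design.bound_dihedral_means)
    means = np.where(bound[:, None],
                     np.asarray(design.bound_dihedral_means)[None, :],
                     np.asarray(design.unbound_dihedral_means)[None, :])
    angles = np.rad2deg(
        rng.vonmises(np.deg2rad(means), design.kappa, size=(design.n_frames, n_dih))
    )
    angles = _wrap_degrees(angles)

    traj = PoseTrajectory(frames=frames, reference=reference,
                          atom_labels=[f"C{i + 1}" for i in range(n_atoms)])
    table = pd.DataFrame({"ligand_id": ligand_id, "frame": np.arange(design.n_frames)})
    for j in range(n_dih):
        table[f"phi{j + 1}"] = angles[:, j]
    return traj, DihedralDataset(data=table)
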