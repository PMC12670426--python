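"""Dissociation-constant fitting from anisotropy titration curves.

Two scikit-learn style regressors carry the curve fits:

* :class:`DirectBindingFP` — protein titrated against fixed probe; fits the
  probe dissociation constant Kd* with the exact quadratic depletion model.
* :class:`CompetitiveBindingFP` — inhibitor titrated against fixed
  protein + probe; fits the inhibitor Kd with the exact ternary model,
  given Kd* from a prior direct fit.

Both fit log10(Kd) (titrations span decades) by bounded least squares with
a multi-start over log-spaced initial guesses, and report asymptotic
standard errors from the Jacobian at the optimum.  Replicate aggregation
follows the per-experiment convention of competitive FP assays: each
independent experiment (its triplicates pooled) is fitted separately and
the cross-experiment mean ± sample SD is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .equilibria import (
    AnisotropyModel,
    _competitive_fb_arrays,
    anisotropy_from_fraction,
    direct_fraction_bound,
)
from .errors import ConvergenceError, ValidationError

__all__ = [
    "TitrationCurve",
    "DirectBindingFP",
    "CompetitiveBindingFP",
    "DirectFitResult",
    "CompetitiveFitResult",
    "ExperimentFit",
    "fit_direct",
    "fit_competitive",
    "aggregate_replicates",
    "fold_selectivity",
    "export_fitted_curve",
]

LOG10_KD_BOUNDS = (-12.0, -1.0)  # Kd bounds 1e-12 .. 1e-1 M, in log10
_ANISOTROPY_BOUNDS = (0.0, 0.4)


@dataclass
class TitrationCurve:
    """A replicate-structured set of anisotropy readings.

    ``data`` must carry columns ``concentration_M`` (titrant, M),
    ``anisotropy``, ``replicate`` and ``experiment``.  In direct mode the
    titrant is protein at fixed ``probe_total``; in competitive mode it is
    inhibitor at fixed ``protein_total`` and ``probe_total``.
    """

    data: pd.DataFrame
    mode: str
    probe_total: float | None = None
    protein_total: float | None = None
    compound: str = ""
    target: str = ""

    REQUIRED_COLUMNS = ("concentration_M", "anisotropy", "replicate", "experiment")

    def __post_init__(self):
        if self.mode not in ("direct", "competitive"):
            raise ValidationError(f"mode must be 'direct' or 'competitive', got {self.mode!r}")
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"titration table is missing columns: {missing}")
        conc = self.data["concentration_M"].to_numpy(dtype=float)
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise ValidationError("concentrations must be finite and >= 0")
        n_distinct = np.unique(conc[conc > 0]).size
        if n_distinct < 6:
            raise ValidationError(
                f"need >= 6 distinct positive concentrations, got {n_distinct}"
            )

    @property
    def experiments(self):
        """Experiment labels in order of first appearance."""
        return list(pd.unique(self.data["experiment"]))

    def experiment_data(self, experiment_id):
        """All points (triplicates pooled) for one experiment."""
        return self.data[self.data["experiment"] == experiment_id]


def _multistart_least_squares(residuals, make_x0, log_kd_grid, bounds):
    """Run bounded least squares from several log10(Kd) starts; keep the best.

    Returns the winning OptimizeResult and the list of all final costs, so
    callers can assert the winner has the lowest residual sum of squares.
    """
    best, costs = None, []
    for log_kd0 in log_kd_grid:
        try:
            res = least_squares(residuals, make_x0(log_kd0), bounds=bounds, method="trf")
        except Exception:
            continue
        costs.append(res.cost)
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise ConvergenceError("all multi-start least-squares attempts failed")
    return best, costs


def _asymptotic_stderr(result, n_obs, n_params):
    """Standard errors from the Jacobian at the optimum (Gauss-Newton)."""
    rss = 2.0 * result.cost
    dof = max(n_obs - n_params, 1)
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se, rss


@dataclass
class DirectFitResult:
    """Probe Kd* and anisotropy endpoints from a direct titration."""

    probe_kd: float
    r_free: float
    r_bound: float
    stderr: dict
    rss: float
    converged: bool
    valid: bool
    plateau_warning: bool
    probe_total: float
    intensity_ratio: float = 1.0

    def predict(self, protein_total):
        """Model anisotropy at the given total protein concentrations."""
        fb = direct_fraction_bound(protein_total, self.probe_total, self.probe_kd)
        model = AnisotropyModel(self.r_free, max(self.r_bound, self.r_free + 1e-12),
                                self.intensity_ratio)
        return anisotropy_from_fraction(fb, model)


@dataclass
class ExperimentFit:
    """One experiment's competitive fit (triplicates pooled)."""

    experiment_id: object
    kd: float
    r_free: float
    r_bound: float
    stderr: dict
    rss: float
    converged: bool
    weak_binder: bool


@dataclass
class CompetitiveFitResult:
    """Per-experiment inhibitor Kds and their mean ± SD."""

    kd_per_experiment: list
    kd_mean: float
    kd_sd: float
    sd_defined: bool
    experiments: list = field(default_factory=list)
    probe_kd: float = float("nan")
    protein_total: float = float("nan")
    probe_total: float = float("nan")
    intensity_ratio: float = 1.0
    compound: str = ""
    target: str = ""

    @property
    def converged(self):
        return all(e.converged for e in self.experiments)

    @property
    def weak_binder(self):
        return any(e.weak_binder for e in self.experiments)

    def predict(self, inhibitor_total, experiment_id=None):
        """Model anisotropy at given inhibitor concentrations.

        Uses one experiment's fitted endpoints if ``experiment_id`` is given,
        otherwise the across-experiment means.
        """
        if experiment_id is None:
            kd = self.kd_mean
            rf = float(np.mean([e.r_free for e in self.experiments]))
            rb = float(np.mean([e.r_bound for e in self.experiments]))
        else:
            exp = next(e for e in self.experiments if e.experiment_id == experiment_id)
            kd, rf, rb = exp.kd, exp.r_free, exp.r_bound
        fb = _competitive_fb_arrays(
            self.protein_total, self.probe_total, np.asarray(inhibitor_total, float),
            self.probe_kd, kd,
        )
        model = AnisotropyModel(rf, max(rb, rf + 1e-12), self.intensity_ratio)
        return anisotropy_from_fraction(np.clip(fb, 0.0, 1.0), model)


class DirectBindingFP(RegressorMixin, BaseEstimator):
    """Quadratic direct-binding fit of a protein-into-probe titration.

    Parameters
    ----------
    probe_total : float
        Fixed total probe concentration (M).
    intensity_ratio : float, default 1.0
        Bound:free fluorescence intensity ratio Q.
    n_starts : int, default 7
        Number of log-spaced log10(Kd*) starting points.
    log_kd_bounds : tuple, default (-12, -1)
        Bounds on log10(Kd* / M).

    Attributes
    ----------
    probe_kd_ : float
        Fitted probe dissociation constant (M).
    r_free_, r_bound_ : float
        Fitted anisotropy plateaus.
    stderr_ : dict
        Asymptotic standard errors for ``probe_kd`` (delta method from
        log10 space), ``r_free`` and ``r_bound``.
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
    valid_ : bool
        False when the fitted plateaus violate r_bound > r_free.
    plateau_warning_ : bool
        True when the top protein concentration is below Kd*/10, i.e. the
        curve never approaches its upper plateau and Kd* is ill-determined.
    """

    def __init__(self, probe_total=20e-9, intensity_ratio=1.0, n_starts=7,
                 log_kd_bounds=LOG10_KD_BOUNDS):
        self.probe_total = probe_total
        self.intensity_ratio = intensity_ratio
        self.n_starts = n_starts
        self.log_kd_bounds = log_kd_bounds

    def _model(self, params, protein_total):
        log_kd, rf, rb = params
        fb = direct_fraction_bound(protein_total, self.probe_total, 10.0 ** log_kd)
        q = self.intensity_ratio
        return (q * fb * rb + (1.0 - fb) * rf) / (q * fb + (1.0 - fb))

    def fit(self, X, y):
        """Fit to protein concentrations ``X`` (M) and anisotropy ``y``."""
        protein = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if protein.size != y.size:
            raise ValidationError("X and y must have equal length")
        if not self.probe_total > 0:
            raise ValidationError("probe_total must be > 0")
        if np.any(protein < 0):
            raise ValidationError("protein concentrations must be >= 0")

        lo, hi = self.log_kd_bounds
        grid = np.linspace(lo + 1.0, hi - 1.0, self.n_starts)
        rf0 = float(np.clip(y.min(), *_ANISOTROPY_BOUNDS))
        rb0 = float(np.clip(y.max(), *_ANISOTROPY_BOUNDS))
        bounds = ([lo, 0.0, 0.0], [hi, 0.4, 0.4])

        def residuals(p):
            return self._model(p, protein) - y

        best, costs = _multistart_least_squares(
            residuals, lambda k0: [k0, rf0, rb0], grid, bounds
        )
        se, rss = _asymptotic_stderr(best, y.size, 3)
        log_kd, rf, rb = best.x
        self.probe_kd_ = 10.0 ** log_kd
        self.r_free_ = float(rf)
        self.r_bound_ = float(rb)
        self.stderr_ = {
            "probe_kd": self.probe_kd_ * math.log(10.0) * se[0],
            "r_free": float(se[1]),
            "r_bound": float(se[2]),
        }
        self.rss_ = rss
        self.multistart_costs_ = costs
        self.converged_ = bool(best.success)
        self.valid_ = self.r_bound_ > self.r_free_
        # The curve has no usable upper plateau when the top protein point
        # sits below Kd*/10, or (equivalently, in the depletion-degenerate
        # family of fits a plateau-free curve admits) when the fitted model
        # reaches under 10% probe saturation at the top of the titration.
        fb_top = direct_fraction_bound(protein.max(), self.probe_total, self.probe_kd_)
        self.plateau_warning_ = bool(
            protein.max() < self.probe_kd_ / 10.0 or fb_top < 0.1
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        protein = np.asarray(X, dtype=float).reshape(-1)
        p = [math.log10(self.probe_kd_), self.r_free_, self.r_bound_]
        return self._model(p, protein)

    def result(self) -> DirectFitResult:
        """Package the fitted attributes as a :class:`DirectFitResult`."""
        return DirectFitResult(
            probe_kd=self.probe_kd_, r_free=self.r_free_, r_bound=self.r_bound_,
            stderr=self.stderr_, rss=self.rss_, converged=self.converged_,
            valid=self.valid_, plateau_warning=self.plateau_warning_,
            probe_total=self.probe_total, intensity_ratio=self.intensity_ratio,
        )


class CompetitiveBindingFP(RegressorMixin, BaseEstimator):
    """Exact-ternary competitive fit of an inhibitor displacement curve.

    Parameters
    ----------
    probe_kd : float
        Probe dissociation constant Kd* (M), from a direct titration.
    protein_total, probe_total : float
        Fixed assay concentrations (M).
    fix_endpoints : tuple or None, default None
        ``(r_free, r_bound)`` to hold the plateaus fixed; by default both
        are floated per curve to absorb plate/day effects.
    weak_inhibition_threshold : float, default 0.2
        Minimum fractional drop of bound probe at the top inhibitor
        concentration; below it the fit is flagged and the Kd is at best a
        lower bound.

    Attributes
    ----------
    kd_ : float
        Fitted inhibitor dissociation constant (M).
    r_free_, r_bound_, stderr_, rss_, converged_ : as in DirectBindingFP.
    weak_binder_ : bool
    """

    def __init__(self, probe_kd=50e-9, protein_total=100e-9, probe_total=20e-9,
                 intensity_ratio=1.0, fix_endpoints=None, n_starts=7,
                 log_kd_bounds=LOG10_KD_BOUNDS, weak_inhibition_threshold=0.2):
        self.probe_kd = probe_kd
        self.protein_total = protein_total
        self.probe_total = probe_total
        self.intensity_ratio = intensity_ratio
        self.fix_endpoints = fix_endpoints
        self.n_starts = n_starts
        self.log_kd_bounds = log_kd_bounds
        self.weak_inhibition_threshold = weak_inhibition_threshold

    def _fb(self, log_kd, inhibitor_total):
        return _competitive_fb_arrays(
            self.protein_total, self.probe_total, inhibitor_total,
            self.probe_kd, 10.0 ** log_kd,
        )

    def _model(self, log_kd, rf, rb, inhibitor_total):
        fb = self._fb(log_kd, inhibitor_total)
        q = self.intensity_ratio
        return (q * fb * rb + (1.0 - fb) * rf) / (q * fb + (1.0 - fb))

    def fit(self, X, y):
        """Fit to inhibitor concentrations ``X`` (M) and anisotropy ``y``."""
        inhibitor = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if inhibitor.size != y.size:
            raise ValidationError("X and y must have equal length")
        for name in ("probe_kd", "protein_total", "probe_total"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if np.any(inhibitor < 0):
            raise ValidationError("inhibitor concentrations must be >= 0")

        lo, hi = self.log_kd_bounds
        positive = inhibitor[inhibitor > 0]
        if positive.size:
            # Start grid spans the sampled decades, padded one decade each way.
            grid = np.linspace(
                max(lo, math.log10(positive.min()) - 1.0),
                min(hi, math.log10(positive.max()) + 1.0),
                self.n_starts,
            )
        else:
            grid = np.linspace(lo + 1.0, hi - 1.0, self.n_starts)

        if self.fix_endpoints is not None:
            rf_fix, rb_fix = self.fix_endpoints

            def residuals(p):
                return self._model(p[0], rf_fix, rb_fix, inhibitor) - y

            best, costs = _multistart_least_squares(
                residuals, lambda k0: [k0], grid, ([lo], [hi])
            )
            se, rss = _asymptotic_stderr(best, y.size, 1)
            log_kd, rf, rb = best.x[0], rf_fix, rb_fix
            se = [se[0], 0.0, 0.0]
        else:
            rf0 = float(np.clip(y.min(), *_ANISOTROPY_BOUNDS))
            rb0 = float(np.clip(y.max() + 0.02, *_ANISOTROPY_BOUNDS))
            bounds = ([lo, 0.0, 0.0], [hi, 0.4, 0.4])

            def residuals(p):
                return self._model(p[0], p[1], p[2], inhibitor) - y

            best, costs = _multistart_least_squares(
                residuals, lambda k0: [k0, rf0, rb0], grid, bounds
            )
            se, rss = _asymptotic_stderr(best, y.size, 3)
            log_kd, rf, rb = best.x

        self.kd_ = 10.0 ** log_kd
        self.r_free_ = float(rf)
        self.r_bound_ = float(rb)
        self.stderr_ = {
            "kd": self.kd_ * math.log(10.0) * float(se[0]),
            "r_free": float(se[1]),
            "r_bound": float(se[2]),
        }
        self.rss_ = rss
        self.multistart_costs_ = costs
        self.converged_ = bool(best.success)
        fb0 = float(self._fb(log_kd, 0.0))
        fb_top = float(self._fb(log_kd, inhibitor.max())) if inhibitor.size else fb0
        inhibition = 1.0 - fb_top / fb0 if fb0 > 0 else 0.0
        self.weak_binder_ = bool(inhibition < self.weak_inhibition_threshold)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        inhibitor = np.asarray(X, dtype=float).reshape(-1)
        return self._model(math.log10(self.kd_), self.r_free_, self.r_bound_, inhibitor)


def fit_direct(curve: TitrationCurve, probe_total=None, **estimator_kwargs) -> DirectFitResult:
    """Fit Kd* from a direct titration curve (all experiments pooled)."""
    if curve.mode != "direct":
        raise ValidationError(f"expected a direct-mode curve, got {curve.mode!r}")
    lt = probe_total if probe_total is not None else curve.probe_total
    if lt is None:
        raise ValidationError("probe_total is required for a direct fit")
    est = DirectBindingFP(probe_total=lt, **estimator_kwargs)
    est.fit(curve.data["concentration_M"].to_numpy(), curve.data["anisotropy"].to_numpy())
    if not est.converged_:
        raise ConvergenceError("direct binding fit did not converge")
    return est.result()


def fit_competitive(curve: TitrationCurve, probe_kd, protein_total=None,
                    probe_total=None, **estimator_kwargs) -> CompetitiveFitResult:
    """Fit inhibitor Kd per experiment, then aggregate as mean ± SD.

    Each experiment's triplicates are pooled into one fit; the reported
    ``kd_mean``/``kd_sd`` are the arithmetic mean and sample SD (n-1) of the
    per-experiment Kds on the linear scale.  A single-experiment curve gets
    ``sd_defined=False`` and NaN SD.
    """
    if curve.mode != "competitive":
        raise ValidationError(f"expected a competitive-mode curve, got {curve.mode!r}")
    pt = protein_total if protein_total is not None else curve.protein_total
    lt = probe_total if probe_total is not None else curve.probe_total
    if pt is None or lt is None:
        raise ValidationError("protein_total and probe_total are required for a competitive fit")

    fits = []
    for exp_id in curve.experiments:
        sub = curve.experiment_data(exp_id)
        est = CompetitiveBindingFP(probe_kd=probe_kd, protein_total=pt,
                                   probe_total=lt, **estimator_kwargs)
        est.fit(sub["concentration_M"].to_numpy(), sub["anisotropy"].to_numpy())
        if not est.converged_:
            raise ConvergenceError(f"competitive fit failed for experiment {exp_id!r}")
        fits.append(ExperimentFit(
            experiment_id=exp_id, kd=est.kd_, r_free=est.r_free_, r_bound=est.r_bound_,
            stderr=est.stderr_, rss=est.rss_, converged=est.converged_,
            weak_binder=est.weak_binder_,
        ))

    kds = [f.kd for f in fits]
    mean, sd = aggregate_replicates(kds)
    return CompetitiveFitResult(
        kd_per_experiment=kds, kd_mean=mean, kd_sd=sd,
        sd_defined=not math.isnan(sd), experiments=fits,
        probe_kd=probe_kd, protein_total=pt, probe_total=lt,
        intensity_ratio=estimator_kwargs.get("intensity_ratio", 1.0),
        compound=curve.compound, target=curve.target,
    )


def aggregate_replicates(kd_per_experiment):
    """Arithmetic mean and sample SD (n-1) of per-experiment Kds.

    Aggregation is on the linear concentration scale, matching the
    mean ± SD convention of competitive-FP affinity tables.  A single
    experiment returns (value, NaN) — the SD is undefined.
    """
    kds = np.asarray(list(kd_per_experiment), dtype=float)
    if kds.size == 0:
        raise ValidationError("need at least one experiment")
    if np.any(kds <= 0) or not np.all(np.isfinite(kds)):
        raise ValidationError("all Kd values must be positive and finite")
    mean = float(kds.mean())
    sd = float(kds.std(ddof=1)) if kds.size > 1 else float("nan")
    return mean, sd


def _round_sig(value, sig_figs):
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + sig_figs - 1)


def fold_selectivity(kd_gal1, kd_gal3c, sig_figs=None):
    """Selectivity ratio Kd(off-target)/Kd(target), here Kd(Gal-1)/Kd(Gal-3C).

    Larger values mean stronger preference for galectin-3C.  With
    ``sig_figs`` the ratio is rounded to that many significant figures for
    table-style reporting.
    """
    if not (kd_gal1 > 0 and kd_gal3c > 0):
        raise ValidationError("both Kd values must be positive")
    ratio = kd_gal1 / kd_gal3c
    if sig_figs is not None:
        if sig_figs < 1:
            raise ValidationError("sig_figs must be >= 1")
        ratio = _round_sig(ratio, sig_figs)
    return ratio


def export_fitted_curve(result, concentration_grid) -> pd.DataFrame:
    """Evaluate a converged fit on a concentration grid.

    Works for :class:`DirectFitResult` (grid = protein totals) and
    :class:`CompetitiveFitResult` (grid = inhibitor totals).  Deterministic
    given the fit; raises :class:`ConvergenceError` on an unconverged fit.
    """
    if not result.converged:
        raise ConvergenceError("cannot export an unconverged fit")
    grid = np.asarray(concentration_grid, dtype=float).reshape(-1)
    return pd.DataFrame({
        "concentration_M": grid,
        "anisotropy": np.asarray(result.predict(grid), dtype=float),
    })
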