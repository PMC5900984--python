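"""Uncertainty and repeatability statistics for the microstructure fits.

The centrepiece is a residual bootstrap stratified by diffusion time: because
the different Delta acquisitions have different SNR (TE grows with Delta),
residuals are exchangeable only within a Delta stratum, so each bootstrap
replicate adds to every fitted value a residual resampled, with replacement,
from the same Delta group only.  95% confidence limits are the 2.5%/97.5%
quantiles of the bootstrap distribution; parameter correlations across
replicates expose the model's degeneracy directions (notably R vs f_i:
larger spheres at higher volume fraction mimic smaller spheres at lower
volume fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimation import ModelFitResult, NormalizedSignalSet, fit_microstructure
from .signals import TwoCompartmentModel

__all__ = [
    "BootstrapResult",
    "StabilityReport",
    "residual_bootstrap",
    "cov_percent",
    "two_sample_ttest",
    "pearson_correlations",
    "r_squared",
    "stereology_correct",
    "repeatability_metrics",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap distribution of refitted parameters.

    ``samples`` is (B_kept, P) in the order of ``param_names``; CIs are the
    2.5/97.5% quantiles (linear interpolation between order statistics at the
    (B+1)p plotting position); ``correlations`` is the Pearson matrix across
    replicates (NaN where a column has zero variance, e.g. D in fixed-D mode).
    """

    samples: np.ndarray
    param_names: tuple[str, ...]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    correlations: np.ndarray
    B: int
    n_dropped: int
    seed: int


def _fit_leverages(model: TwoCompartmentModel, fit: ModelFitResult) -> np.ndarray:
    """Diagonal of the hat matrix J (J^T J)^-1 J^T for the linearized model.

    J is the finite-difference Jacobian of the predicted signals with respect
    to the free parameters at the point estimate.
    """
    p = fit.params
    theta = [p.R, p.f_i] if fit.mode == "fixed-D" else [p.R, p.f_i, p.D]

    def predict(t):
        if fit.mode == "fixed-D":
            return model.predict(t[0], t[1], p.D)
        return model.predict(t[0], t[1], t[2])

    f0 = predict(theta)
    J = np.empty((f0.size, len(theta)))
    for j, val in enumerate(theta):
        step = 1e-6 * max(abs(val), 1e-3)
        tp = list(theta)
        tp[j] = val + step
        J[:, j] = (predict(tp) - f0) / step
    # pinv guards against rank deficiency at a constraint or degeneracy
    H = J @ np.linalg.pinv(J.T @ J) @ J.T
    return np.diag(H).copy()


@dataclass
class StabilityReport:
    """Longitudinal stability summary across scan sessions.

    ``table`` has one row per session; ``cov`` maps quantity name to CoV (%);
    ``ttests`` maps comparison name to (t, p); ``repeatability`` is the mean
    absolute percentage difference over repeated-scan pairs, if any.
    """

    table: "object"                     # pandas.DataFrame
    cov: dict[str, float]
    ttests: dict[str, tuple[float, float]]
    repeatability: float | None = None


def _resample_residuals(
    residuals: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Resample residuals with replacement within each stratum.

    Position i of the result is drawn only from residual positions j with
    strata[j] == strata[i]; residuals never cross strata.
    """
    out = np.empty_like(residuals)
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        out[idx] = residuals[idx[rng.integers(0, idx.size, size=idx.size)]]
    return out


def residual_bootstrap(
    fit: ModelFitResult,
    s: NormalizedSignalSet,
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    max_dropped_fraction: float = 0.05,
    residual_correction: str = "leverage",
) -> BootstrapResult:
    """Delta-stratified residual bootstrap of a whole-ROI model fit.

    Residuals (observed - fitted, over the fitting entries) are resampled with
    replacement within each Delta stratum; each replicate dataset
    ``fitted + resampled residual`` is refitted in the same mode.  Refits use
    ``n_starts`` starting points: the point estimate as a warm start plus
    ``n_starts - 1`` seeded random starts (the full multistart is available by
    raising ``n_starts``).  Replicates whose refit fails are dropped and
    counted; more than ``max_dropped_fraction`` dropped is an error.

    With few data points per fitted parameter, raw least-squares residuals
    systematically understate the noise SD, which would shrink the bootstrap
    intervals; ``residual_correction`` selects the standard remedy applied to
    the residual pool before resampling:

    * ``"leverage"`` (default): modified residuals r_i / sqrt(1 - h_i), with
      leverages h_i from the hat matrix of the model Jacobian linearized at
      the point estimate;
    * ``"dof"``: the global factor sqrt(n / (n - p));
    * ``"none"``: the raw residuals.
    """
    if B < 2:
        raise ValueError(f"need B >= 2 bootstrap samples, got {B}")
    observed = fit.observed
    fitted = fit.fitted
    strata = s.fitting_deltas
    if observed.size != strata.size:
        raise ValueError("fit and signal set disagree on the fitting entries")
    for val in np.unique(strata):
        if np.sum(strata == val) < 2:
            raise ValueError(f"Delta={val} ms stratum has < 2 residuals")
    residuals = observed - fitted
    model = TwoCompartmentModel(s.fitting_measurements, gamma=s.gamma)
    n_pts = residuals.size
    n_par = 2 if fit.mode == "fixed-D" else 3
    if residual_correction == "leverage":
        h = _fit_leverages(model, fit)
        residuals = residuals / np.sqrt(1.0 - np.clip(h, 0.0, 0.95))
    elif residual_correction == "dof":
        if n_pts > n_par:
            residuals = residuals * math.sqrt(n_pts / (n_pts - n_par))
    elif residual_correction != "none":
        raise ValueError(f"unknown residual_correction {residual_correction!r}")
    warm = fit.params.as_array()
    fixed_D = fit.params.D if fit.mode == "fixed-D" else None
    param_names = ("R", "f_i") if fit.mode == "fixed-D" else ("R", "f_i", "D")

    rng = np.random.default_rng(seed)
    rows = []
    dropped = 0
    for _ in range(B):
        new_values = fitted + _resample_residuals(residuals, strata, rng)
        replicate = NormalizedSignalSet(
            measurements=s.fitting_measurements,
            values=new_values,
            raw=new_values,
            fit_mask=np.ones(new_values.size, dtype=bool),
            gamma=s.gamma,
        )
        try:
            refit = fit_microstructure(
                replicate,
                mode=fit.mode,
                fixed_D=fixed_D,
                n_starts=n_starts - 1,
                seed=int(rng.integers(0, 2**31 - 1)),
                model=model,
                x0=warm,
            )
        except (ValueError, RuntimeError):
            dropped += 1
            continue
        p = refit.params
        rows.append([getattr(p, name) for name in param_names])
    if dropped > max_dropped_fraction * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap refits failed")
    samples = np.array(rows)
    # (B+1)p plotting position ("weibull"), the bootstrap-literature convention
    # for percentile intervals; linear interpolation between order statistics
    lo = np.percentile(samples, 2.5, axis=0, method="weibull")
    hi = np.percentile(samples, 97.5, axis=0, method="weibull")
    return BootstrapResult(
        samples=samples,
        param_names=param_names,
        ci_lower=dict(zip(param_names, lo.tolist())),
        ci_upper=dict(zip(param_names, hi.tolist())),
        correlations=pearson_correlations(samples),
        B=B,
        n_dropped=dropped,
        seed=seed,
    )


def cov_percent(values: np.ndarray) -> float:
    """Coefficient of variation, 100 * sample SD (n-1) / mean, in percent."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a CoV")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student form by default.

    Returns (t, p).  Set ``welch`` for the unequal-variance form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def pearson_correlations(samples: np.ndarray) -> np.ndarray:
    """Pearson product-moment correlation matrix of a (B, P) sample table.

    Symmetric with unit diagonal; entries involving a zero-variance column
    are NaN (flagged undefined) rather than raising.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise ValueError("need a (B >= 3, P) sample table")
    sd = samples.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(samples, rowvar=False)
    corr = np.atleast_2d(corr)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the mean)."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("need equal-length sequences of >= 2 values")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero observed variance")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def stereology_correct(mean_thickness: float) -> float:
    """Correct a mean planar-section thickness for oblique sectioning: t * pi/4.

    Random planar sections cut shells at oblique angles, overestimating the
    true wall thickness; the stereological correction multiplies by pi/4.
    """
    if mean_thickness < 0:
        raise ValueError(f"thickness must be non-negative, got {mean_thickness}")
    return mean_thickness * math.pi / 4.0


def repeatability_metrics(pairs: np.ndarray) -> float:
    """Mean absolute percentage difference over (first, repeat) measurement pairs.

    Each pair contributes 100 * |a - b| / ((a + b)/2); the reference is the
    pair mean, so the metric is symmetric in the pair members.
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[1] != 2:
        raise ValueError("expected a sequence of (first, repeat) pairs")
    if np.any(pairs <= 0):
        raise ValueError("measurements must be positive")
    a, b = pairs[:, 0], pairs[:, 1]
    return float(np.mean(100.0 * np.abs(a - b) / ((a + b) / 2.0)))
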