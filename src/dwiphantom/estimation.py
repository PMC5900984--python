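"""Noise estimation, Rician ML ADC mapping, signal conditioning, and
constrained multistart fitting of the two-compartment microstructure model.

Noise handling follows the standard magnitude-MRI treatment: the Gaussian
noise SD is sigma = S_bg * sqrt(2/pi) where S_bg is the mean magnitude in a
signal-free background ROI (the background-only magnitude is Rayleigh
distributed with mean sigma * sqrt(pi/2)).  ADC maps are fitted per voxel by
maximizing the Rician likelihood of the observed magnitudes, which removes the
upward noise-floor bias that plain least squares on magnitudes suffers at low
SNR.  The microstructure model is fitted by least squares on per-Delta
normalized signals (averaging/normalization makes a single Rician PDF an
invalid likelihood), with low-signal points discarded below 2 * S_noise, and a
multistart Nelder-Mead search constrained to a plausible biological box via a
smooth logistic reparameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e

from .protocol import GYROMAGNETIC_RATIO_PROTON, PGSEMeasurement, Protocol
from .signals import FIT_BOUNDS, MicrostructureParams, TwoCompartmentModel

__all__ = [
    "NoiseEstimate",
    "ADCFitResult",
    "NormalizedSignalSet",
    "ExclusionReport",
    "ModelFitResult",
    "estimate_noise",
    "fit_adc_ml",
    "fit_adc_loglinear",
    "normalize_per_delta",
    "filter_low_signals",
    "fit_microstructure",
    "fit_microstructure_voxelwise",
    "roi_average_signals",
]


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseEstimate:
    """Rician noise summary: sigma = S_bg * sqrt(2/pi); SNR = S_b0 / sigma."""

    sigma: float
    S_bg: float
    S_noise: float
    SNR: float
    snr_per_delta: dict[float, float] = field(default_factory=dict)


def estimate_noise(
    volume: np.ndarray,
    background_mask: np.ndarray,
    analysis_mask: np.ndarray,
    protocol: Protocol,
    noise_mask: np.ndarray | None = None,
) -> NoiseEstimate:
    """Estimate sigma, S_noise and SNR from a 4D magnitude image.

    ``background_mask`` selects signal-free voxels; sigma is the mean
    background magnitude (over all volumes) times sqrt(2/pi).  ``S_noise``
    defaults to the same background mean (one ROI serves as both background
    and noise ROI) unless a separate ``noise_mask`` is supplied.  SNR is the
    mean b = 0 signal in ``analysis_mask`` divided by sigma; per-Delta SNRs
    use each Delta group's own G = 0 volume(s).
    """
    volume = np.asarray(volume, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("background mask is empty")
    if not analysis_mask.any():
        raise ValueError("analysis mask is empty")
    if np.any(background_mask & analysis_mask):
        raise ValueError("background ROI overlaps the analysis ROI")
    S_bg = float(volume[background_mask].mean())
    sigma = S_bg * math.sqrt(2.0 / math.pi)
    if sigma <= 0:
        raise ValueError("background signal is zero; cannot estimate noise")
    if noise_mask is not None:
        noise_mask = np.asarray(noise_mask, dtype=bool)
        if not noise_mask.any():
            raise ValueError("noise mask is empty")
        S_noise = float(volume[noise_mask].mean())
    else:
        S_noise = S_bg
    G = protocol.G_values
    b0_idx = np.nonzero(G == 0)[0]
    if b0_idx.size == 0:
        raise ValueError("protocol has no G=0 (b=0) measurement; SNR undefined")
    S_b0 = float(volume[analysis_mask][:, b0_idx].mean())
    snr_per_delta = {}
    for Delta, idx in protocol.delta_groups().items():
        z = idx[G[idx] == 0]
        if z.size:
            snr_per_delta[Delta] = float(volume[analysis_mask][:, z].mean()) / sigma
    return NoiseEstimate(sigma, S_bg, S_noise, S_b0 / sigma, snr_per_delta)


# --------------------------------------------------------------------------
# ADC fitting
# --------------------------------------------------------------------------

@dataclass
class ADCFitResult:
    """Per-voxel mono-exponential fit: ADC (um^2/ms), S0, convergence flags."""

    ADC: np.ndarray
    S0: np.ndarray
    converged: np.ndarray
    at_bound: np.ndarray  # ADC pinned at its non-negativity bound


def fit_adc_loglinear(signals: np.ndarray, b_values: Sequence[float]) -> ADCFitResult:
    """Log-linear least-squares ADC (the classic estimator; Rician-biased at low SNR).

    ``signals``: (n_voxels, n_b) magnitudes; ``b_values`` in s/mm^2.  Fits
    log S = log S0 - b * ADC * 1e-3 by ordinary least squares on voxels with
    all-positive signals.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    b = np.asarray(b_values, dtype=float)
    if signals.shape[1] != b.size:
        raise ValueError("signal/b-value length mismatch")
    n = signals.shape[0]
    adc = np.zeros(n)
    s0 = np.zeros(n)
    ok = np.all(signals > 0, axis=1)
    if ok.any():
        X = np.column_stack([np.ones_like(b), -b * 1e-3])
        coef, *_ = np.linalg.lstsq(X, np.log(signals[ok]).T, rcond=None)
        s0[ok] = np.exp(coef[0])
        adc[ok] = coef[1]
    return ADCFitResult(ADC=adc, S0=s0, converged=ok, at_bound=np.zeros(n, dtype=bool))


def _rician_nll(
    theta: np.ndarray, s: np.ndarray, b: np.ndarray, sigma: float, adc_max: float = np.inf
) -> float:
    S0, adc = theta
    if S0 <= 0 or adc < 0 or adc > adc_max:
        return np.inf
    nu = S0 * np.exp(-b * adc * 1e-3)
    z = s * nu / sigma**2
    # log I0(z) = z + log(i0e(z)), numerically safe for large z
    log_i0 = z + np.log(i0e(z))
    nll = np.sum((s**2 + nu**2) / (2.0 * sigma**2) - log_i0)
    return float(nll)


def fit_adc_ml(
    signals: np.ndarray,
    b_values: Sequence[float],
    sigma: float,
    adc_max: float = 4.0,
    adc_bound_tol: float = 1e-3,
) -> ADCFitResult:
    """Maximum-likelihood Rician ADC fit, voxel by voxel.

    For each voxel, (S0, ADC) maximize the product of Rician likelihoods of
    the observed magnitudes given mean S0 * exp(-b * ADC * 1e-3) and noise
    scale ``sigma``.  Optimization is Nelder-Mead started from the log-linear
    least-squares estimate.  ADC is constrained to [0, ``adc_max``] um^2/ms
    (default 4, comfortably above free water): at very low SNR the unbounded
    Rician likelihood has heavy-tailed maxima where high-b points are
    explained as pure noise, so a plausible physical range is imposed just as
    for the microstructure parameters.  Non-convergent voxels are flagged,
    not zeroed; voxels pinned at either ADC limit are flagged at-bound.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    b = np.asarray(b_values, dtype=float)
    if np.unique(b).size < 3 or not np.any(b == 0):
        raise ValueError("need >= 3 distinct b-values including b = 0")
    init = fit_adc_loglinear(np.clip(signals, 1e-12, None), b)
    n = signals.shape[0]
    adc = np.zeros(n)
    s0 = np.zeros(n)
    converged = np.zeros(n, dtype=bool)
    for v in range(n):
        s = signals[v]
        if np.all(s == 0):
            continue  # flagged non-converged
        S0_init = max(float(np.mean(s[b == 0])), 1e-6)
        adc_init = float(np.clip(init.ADC[v], 1e-4, adc_max * 0.9)) if init.converged[v] else 1.0
        x0 = np.array([S0_init, adc_init])
        f0 = _rician_nll(x0, s, b, sigma, adc_max)
        fatol = max(1e-10, 1e-12 * abs(f0))
        res = minimize(
            _rician_nll,
            x0=x0,
            args=(s, b, sigma, adc_max),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": fatol, "maxiter": 4000},
        )
        if np.isfinite(res.fun):
            s0[v], adc[v] = res.x
            adc[v] = min(max(adc[v], 0.0), adc_max)
            converged[v] = bool(res.success)
    at_bound = converged & ((adc < adc_bound_tol) | (adc >= adc_max * 0.99))
    return ADCFitResult(ADC=adc, S0=s0, converged=converged, at_bound=at_bound)


# --------------------------------------------------------------------------
# normalization and filtering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedSignalSet:
    """Per-Delta normalized signals paired with their measurements.

    ``values`` are signals divided by the G = 0 reference of their Delta group
    (so G = 0 entries are exactly 1); ``raw`` keeps the unnormalized
    magnitudes for the low-signal exclusion rule; ``fit_mask`` marks entries
    that enter the fit (G > 0).
    """

    measurements: tuple[PGSEMeasurement, ...]
    values: np.ndarray
    raw: np.ndarray
    fit_mask: np.ndarray
    gamma: float = GYROMAGNETIC_RATIO_PROTON

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def fitting_measurements(self) -> tuple[PGSEMeasurement, ...]:
        return tuple(m for m, f in zip(self.measurements, self.fit_mask) if f)

    @property
    def fitting_values(self) -> np.ndarray:
        return self.values[self.fit_mask]

    @property
    def fitting_deltas(self) -> np.ndarray:
        return np.array([m.Delta for m in self.fitting_measurements])

    def subset(self, keep: np.ndarray) -> "NormalizedSignalSet":
        keep = np.asarray(keep)
        return NormalizedSignalSet(
            tuple(m for m, k in zip(self.measurements, keep) if k),
            self.values[keep],
            self.raw[keep],
            self.fit_mask[keep],
            self.gamma,
        )

    def drop_longest_delta(self) -> "NormalizedSignalSet":
        longest = max(m.Delta for m in self.measurements)
        return self.subset(np.array([m.Delta != longest for m in self.measurements]))


def normalize_per_delta(signals: Sequence[float], protocol: Protocol) -> NormalizedSignalSet:
    """Normalize each Delta group's signals to its G = 0 scan.

    Removes per-Delta amplitude differences (e.g. TE-dependent T2 weighting).
    G = 0 entries are retained with value 1 but marked non-fitting.  Raises if
    any Delta group lacks a positive G = 0 reference.
    """
    values = np.asarray(signals, dtype=float)
    if values.ndim != 1 or values.size != len(protocol):
        raise ValueError("signal vector length must match the protocol")
    G = protocol.G_values
    normalized = np.empty_like(values)
    for Delta, idx in protocol.delta_groups().items():
        zero = idx[G[idx] == 0]
        if zero.size == 0:
            raise ValueError(f"no G=0 reference for Delta={Delta} ms")
        ref = float(values[zero].mean())
        if ref <= 0:
            raise ValueError(f"non-positive G=0 reference for Delta={Delta} ms")
        normalized[idx] = values[idx] / ref
    return NormalizedSignalSet(
        measurements=tuple(protocol.measurements),
        values=normalized,
        raw=values.copy(),
        fit_mask=G > 0,
        gamma=protocol.gamma,
    )


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for the 2*S_noise low-signal exclusion rule."""

    threshold: float
    excluded: tuple[tuple[float, float], ...]   # (G, Delta) pairs removed
    retained: int
    total: int


def filter_low_signals(
    s: NormalizedSignalSet,
    S_noise: float,
) -> tuple[NormalizedSignalSet, ExclusionReport]:
    """Discard fitting entries whose raw magnitude is strictly below 2 * S_noise.

    The exclusion is judged on the unnormalized signal; equality retains the
    point.  G = 0 reference entries are never removed.  Raises if no fitting
    entry survives.
    """
    if S_noise <= 0:
        raise ValueError(f"S_noise must be positive, got {S_noise}")
    threshold = 2.0 * S_noise
    drop = s.fit_mask & (s.raw < threshold)
    keep = ~drop
    filtered = s.subset(keep)
    if not filtered.fit_mask.any():
        raise ValueError("all fitting entries fall below 2*S_noise; data unfittable")
    excluded = tuple((m.G, m.Delta) for m, d in zip(s.measurements, drop) if d)
    return filtered, ExclusionReport(
        threshold=threshold,
        excluded=excluded,
        retained=int(keep.sum()),
        total=len(s),
    )


# --------------------------------------------------------------------------
# microstructure fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFitResult:
    """Best-of-multistart constrained least-squares fit of the two-compartment model."""

    params: MicrostructureParams
    mode: str                       # "all-free" or "fixed-D"
    objective: float                # residual sum of squares
    r_squared: float
    at_bound: dict[str, bool]
    n_starts: int
    seed: int
    fitted: np.ndarray              # model prediction at the fitting entries
    observed: np.ndarray            # observed normalized signals (fitting entries)


_BOUND_NAMES = ("R", "f_i", "D")


def _to_unconstrained(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((p - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.log(frac / (1.0 - frac))


def _to_box(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return lo + (hi - lo) * expit(z)


def _at_bound_flags(params: dict[str, float]) -> dict[str, bool]:
    # "within 1% of the constraints": value within 1% (relative) of either bound
    flags = {}
    for name, val in params.items():
        lo, hi = FIT_BOUNDS[name]
        flags[name] = bool(val <= lo * 1.01 or val >= hi * 0.99)
    return flags


def r_squared_of_fit(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_microstructure(
    s: NormalizedSignalSet,
    mode: str = "all-free",
    fixed_D: float | None = None,
    n_starts: int = 100,
    seed: int = 0,
    model: TwoCompartmentModel | None = None,
    x0: np.ndarray | None = None,
    engine: str = "compiled",
) -> ModelFitResult:
    """Fit (R, f_i, D) — or (R, f_i) with D fixed — to normalized signals.

    Minimizes the sum of squared differences between observed normalized
    signals and the two-compartment prediction, over ``n_starts`` Nelder-Mead
    runs started uniformly within the constraint box (seeded), keeping the
    lowest-objective solution.  The box constraints are enforced through a
    smooth logistic transform so the simplex itself is unconstrained;
    at-bound flags are evaluated on the back-transformed parameters.

    ``x0`` optionally prepends a warm start (in parameter space) to the random
    starts, as used by the bootstrap refits.  ``engine`` selects the
    JIT-compiled simplex loop ("compiled", default) or scipy's Nelder-Mead
    ("scipy"); the two implement the same algorithm and tolerances and are
    cross-checked in the test suite.
    """
    if mode not in ("all-free", "fixed-D"):
        raise ValueError(f"unknown mode {mode!r}")
    if (mode == "fixed-D") != (fixed_D is not None):
        raise ValueError("fixed_D must be supplied iff mode='fixed-D'")
    if engine not in ("compiled", "scipy"):
        raise ValueError(f"unknown engine {engine!r}")
    obs = s.fitting_values
    free_names = ["R", "f_i"] if mode == "fixed-D" else ["R", "f_i", "D"]
    if obs.size < len(free_names):
        raise ValueError(
            f"{obs.size} fitting entries cannot constrain {len(free_names)} parameters"
        )
    if mode == "all-free" and np.unique(s.fitting_deltas).size < 2:
        raise ValueError("all-free mode needs fitting entries spanning >= 2 Delta values")
    if model is None:
        model = TwoCompartmentModel(s.fitting_measurements, gamma=s.gamma)
    lo = np.array([FIT_BOUNDS[n][0] for n in free_names])
    hi = np.array([FIT_BOUNDS[n][1] for n in free_names])
    D_fix = float(fixed_D) if mode == "fixed-D" else None

    rng = np.random.default_rng(seed)
    starts = lo + (hi - lo) * rng.random((n_starts, len(free_names)))
    if x0 is not None:
        starts = np.vstack([np.asarray(x0, dtype=float)[None, : len(free_names)], starts])
    starts_z = _to_unconstrained(starts, lo, hi)

    if engine == "compiled":
        from ._nm import fit_multistart_compiled

        z_best, f_best = fit_multistart_compiled(
            starts_z, lo, hi, D_fix, model, obs,
            xatol=1e-8, fatol=1e-8, maxiter=2000,
        )
        if not np.isfinite(f_best):
            raise RuntimeError("objective non-finite at every start")
        best_x, best_fun = z_best, float(f_best)
    else:
        if mode == "fixed-D":

            def objective(z: np.ndarray) -> float:
                R, f_i = _to_box(z, lo, hi)
                resid = model.predict(R, f_i, D_fix) - obs
                return float(resid @ resid)

        else:

            def objective(z: np.ndarray) -> float:
                R, f_i, D = _to_box(z, lo, hi)
                resid = model.predict(R, f_i, D) - obs
                return float(resid @ resid)

        best = None
        for start_z in starts_z:
            res = minimize(
                objective,
                x0=start_z,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("objective non-finite at every start")
        best_x, best_fun = best.x, float(best.fun)
    theta = _to_box(best_x, lo, hi)
    if mode == "fixed-D":
        params = MicrostructureParams(R=theta[0], f_i=theta[1], D=D_fix)
        at_bound = _at_bound_flags({"R": theta[0], "f_i": theta[1]})
        at_bound["D"] = False  # fixed, not estimated
    else:
        params = MicrostructureParams(R=theta[0], f_i=theta[1], D=theta[2])
        at_bound = _at_bound_flags(dict(zip(free_names, theta)))
    fitted = model.predict(params.R, params.f_i, params.D)
    return ModelFitResult(
        params=params,
        mode=mode,
        objective=best_fun,
        r_squared=r_squared_of_fit(obs, fitted),
        at_bound=at_bound,
        n_starts=int(len(starts)),
        seed=seed,
        fitted=fitted,
        observed=obs,
    )


def roi_average_signals(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean raw magnitude over the mask, one value per volume (4th axis)."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return volume[mask].mean(axis=0)


@dataclass
class VoxelwiseFitSummary:
    """At-bound fractions and median +/- IQR per parameter, with and without
    at-bound voxels (the voxelwise reporting convention for poor-precision fits)."""

    at_bound_fraction: dict[str, float]
    median_iqr_all: dict[str, tuple[float, float]]
    median_iqr_excluding_bound: dict[str, tuple[float, float]]
    n_voxels: int
    n_any_at_bound: int


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def fit_microstructure_voxelwise(
    volume: np.ndarray,
    mask: np.ndarray,
    protocol: Protocol,
    mode: str = "all-free",
    fixed_D: float | None = None,
    n_starts: int = 100,
    seed: int = 0,
    S_noise: float | None = None,
) -> tuple[dict[str, np.ndarray], VoxelwiseFitSummary]:
    """Per-voxel two-compartment fits over a mask.

    Each voxel's signal vector is normalized per Delta, optionally filtered at
    2 * S_noise, and fitted by least squares (no averaging, so the Rician-ML
    argument for ADC does not apply here).  Returns parameter maps (R, f_i, D,
    r_squared, plus boolean at-bound maps) and a summary with at-bound voxel
    fractions and median +/- IQR per parameter including/excluding at-bound
    voxels.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    shape = mask.shape
    maps = {
        name: np.full(shape, np.nan)
        for name in ("R", "f_i", "D", "r_squared")
    }
    bound_maps = {name: np.zeros(shape, dtype=bool) for name in _BOUND_NAMES}
    idx = np.argwhere(mask)
    model_cache: dict[tuple, TwoCompartmentModel] = {}
    for j, vox in enumerate(idx):
        sig = volume[tuple(vox)]
        try:
            nset = normalize_per_delta(sig, protocol)
            if S_noise is not None:
                nset, _ = filter_low_signals(nset, S_noise)
            key = nset.fitting_measurements
            if key not in model_cache:
                model_cache[key] = TwoCompartmentModel(key, gamma=protocol.gamma)
            fit = fit_microstructure(
                nset, mode=mode, fixed_D=fixed_D, n_starts=n_starts,
                seed=seed + j, model=model_cache[key],
            )
        except (ValueError, RuntimeError):
            continue
        t = tuple(vox)
        maps["R"][t] = fit.params.R
        maps["f_i"][t] = fit.params.f_i
        maps["D"][t] = fit.params.D
        maps["r_squared"][t] = fit.r_squared
        for name in _BOUND_NAMES:
            bound_maps[name][t] = fit.at_bound[name]
    maps.update({f"{k}_at_bound": v for k, v in bound_maps.items()})
    fitted_mask = mask & np.isfinite(maps["R"])
    n_vox = int(fitted_mask.sum())
    any_bound = np.zeros(shape, dtype=bool)
    for name in _BOUND_NAMES:
        any_bound |= bound_maps[name]
    frac = {
        name: (float(bound_maps[name][fitted_mask].mean()) if n_vox else float("nan"))
        for name in _BOUND_NAMES
    }
    med_all = {name: _median_iqr(maps[name][fitted_mask]) for name in _BOUND_NAMES}
    good = fitted_mask & ~any_bound
    med_ex = {name: _median_iqr(maps[name][good]) for name in _BOUND_NAMES}
    summary = VoxelwiseFitSummary(
        at_bound_fraction=frac,
        median_iqr_all=med_all,
        median_iqr_excluding_bound=med_ex,
        n_voxels=n_vox,
        n_any_at_bound=int(any_bound[fitted_mask].sum()),
    )
    return maps, summary
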