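"""Forward PGSE signal models for the two-compartment microsphere phantom.

The normalized signal is a convex mixture of restricted diffusion inside an
impermeable sphere of radius R (Gaussian phase distribution, GPD, evaluated as
a series over Bessel-root modes) and hindered extracellular diffusion with the
diffusivity reduced by the tortuosity factor 1 + f_i/2:

    S/S0 = f_i * S_i(R, D)  +  (1 - f_i) * S_e(D, f_i)

    S_i  = exp( -2 gamma^2 G^2 sum_m  [alpha_m^2 (alpha_m^2 R^2 - 2)]^-1 *
             [ 2 delta / (alpha_m^2 D)
               + ( -2 + 2 e^{-alpha_m^2 D delta} + 2 e^{-alpha_m^2 D Delta}
                   - e^{-alpha_m^2 D (Delta-delta)} - e^{-alpha_m^2 D (Delta+delta)}
                 ) / (alpha_m^4 D^2) ] )

    S_e  = exp( -b D / (1 + f_i/2) )

where alpha_m R is the m-th positive root of x J'_{3/2}(x) - (1/2) J_{3/2}(x) = 0
(J_{3/2}: Bessel function of the first kind, order 3/2).  A single free
diffusivity D is shared by both compartments; signals are magnitudes with no
direction dependence (spherical symmetry), and no T2 weighting enters the model
(per-Delta normalization absorbs TE differences downstream).

Units: R in um, D in um^2/ms, b in s/mm^2; note b * D * 1e-3 is the
dimensionless free-diffusion exponent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import bisect
from scipy.special import jv, jvp

from .protocol import GYROMAGNETIC_RATIO_PROTON, PGSEMeasurement, Protocol

__all__ = [
    "MicrostructureParams",
    "FIT_BOUNDS",
    "BesselRootTable",
    "bessel_roots",
    "sphere_signal",
    "hindered_signal",
    "two_compartment_signal",
    "free_signal",
    "TwoCompartmentModel",
]

#: Constrained-fit box: plausible biological limits on (R, f_i, D).
FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "R": (0.1, 25.0),       # um
    "f_i": (0.01, 1.0),
    "D": (0.1, 3.0),        # um^2/ms
}


@dataclass(frozen=True)
class MicrostructureParams:
    """Model parameters: sphere radius R (um), intra-sphere volume fraction f_i,
    free diffusivity D (um^2/ms)."""

    R: float
    f_i: float
    D: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"sphere radius must be positive, got R={self.R}")
        if not (0.0 <= self.f_i <= 1.0):
            raise ValueError(f"volume fraction must lie in [0, 1], got f_i={self.f_i}")
        if self.D <= 0:
            raise ValueError(f"diffusivity must be positive, got D={self.D}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.f_i, self.D])


@dataclass(frozen=True)
class BesselRootTable:
    """First ``count`` positive roots x_m of x J'_{3/2}(x) - (1/2) J_{3/2}(x) = 0.

    The roots are dimensionless; the GPD mode wavenumbers are alpha_m = x_m / R.
    """

    roots: np.ndarray
    count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "roots", np.asarray(self.roots, dtype=float))
        if len(self.roots) != self.count:
            raise ValueError("root count mismatch")
        if np.any(self.roots <= 0) or np.any(np.diff(self.roots) <= 0):
            raise ValueError("roots must be positive and strictly increasing")


def _root_function(x: float) -> float:
    return x * jvp(1.5, x) - 0.5 * jv(1.5, x)


@lru_cache(maxsize=None)
def _cached_roots(count: int) -> tuple[float, ...]:
    # Sign-change scan with step 0.1, then bisection; roots are ~pi apart so the
    # scan cannot skip any.  Robustness over speed: computed once per count.
    roots: list[float] = []
    lo, step = 0.05, 0.1
    f_lo = _root_function(lo)
    while len(roots) < count:
        hi = lo + step
        f_hi = _root_function(hi)
        if np.sign(f_lo) != np.sign(f_hi):
            roots.append(bisect(_root_function, lo, hi, xtol=1e-10))
        lo, f_lo = hi, f_hi
    return tuple(roots)


def bessel_roots(count: int = 20) -> BesselRootTable:
    """First ``count`` positive roots of x J'_{3/2}(x) - (1/2) J_{3/2}(x) = 0.

    Each root is accurate to better than 1e-8 absolute; results are cached.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    return BesselRootTable(np.array(_cached_roots(count)), count)


def _gpd_log_attenuation(
    G_si: np.ndarray,
    delta_s: np.ndarray,
    Delta_s: np.ndarray,
    R_m: float,
    D_si: float,
    x: np.ndarray,
    gamma: float,
    rtol: float | None = None,
) -> np.ndarray:
    """log S_i for arrays of measurements (SI units; x: root table values).

    When ``rtol`` is given the series is truncated at the first mode whose
    absolute term falls below ``rtol`` times the running partial sum of the
    exponent, uniformly over the measurement set.
    """
    x = x[:, None]                                  # (M, 1)
    u = (x / R_m) ** 2 * D_si                       # alpha_m^2 D, 1/s, (M, 1)
    pref = R_m**2 / (x**2 * (x**2 - 2.0))           # (M, 1)
    d = delta_s[None, :]
    De = Delta_s[None, :]
    term = 2.0 * d / u + (
        -2.0
        + 2.0 * np.exp(-u * d)
        + 2.0 * np.exp(-u * De)
        - np.exp(-u * (De - d))
        - np.exp(-u * (De + d))
    ) / u**2                                        # (M, K)
    terms = pref * term                             # (M, K)
    if rtol is not None and terms.shape[0] > 1:
        partial = np.cumsum(terms, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(terms[1:]) / np.maximum(np.abs(partial[:-1]), 1e-300)
        small = np.all(rel < rtol, axis=1)
        if np.any(small):
            cutoff = int(np.argmax(small)) + 1
            terms = terms[:cutoff]
    return -2.0 * gamma**2 * G_si**2 * terms.sum(axis=0)


def sphere_signal(
    m: PGSEMeasurement,
    R: float,
    D: float,
    roots: BesselRootTable | None = None,
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
    series_rtol: float = 1e-8,
) -> float:
    """GPD signal for diffusion restricted in an impermeable sphere, in (0, 1].

    Parameters
    ----------
    m : PGSE measurement (G in mT/m, delta/Delta in ms).
    R : sphere radius in um.
    D : intrinsic diffusivity in um^2/ms.
    roots : Bessel-root table (>= 10 roots); default first 20 roots.
    series_rtol : terminate the mode series once a term's relative contribution
        to the exponent falls below this, or when roots are exhausted.
    """
    if R <= 0 or D <= 0:
        raise ValueError(f"R and D must be positive, got R={R}, D={D}")
    if roots is None:
        roots = bessel_roots(20)
    if roots.count < 10:
        raise ValueError("need at least 10 Bessel roots for model evaluation")
    if m.G == 0:
        return 1.0
    log_s = _gpd_log_attenuation(
        np.array([m.G * 1e-3]),
        np.array([m.delta * 1e-3]),
        np.array([m.Delta * 1e-3]),
        R * 1e-6,
        D * 1e-9,
        roots.roots,
        gamma,
        rtol=series_rtol,
    )
    return float(np.exp(log_s[0]))


def hindered_signal(
    m: PGSEMeasurement,
    D: float,
    f_i: float,
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
) -> float:
    """Hindered extracellular signal exp(-b D / (1 + f_i/2)), in (0, 1].

    The tortuosity factor 1 + f_i/2 models obstruction by spheres at volume
    fraction f_i; f_i = 0 recovers free diffusion.
    """
    if not (0.0 <= f_i <= 1.0):
        raise ValueError(f"f_i must lie in [0, 1], got {f_i}")
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    b = m.b(gamma)
    return float(np.exp(-b * (D / (1.0 + f_i / 2.0)) * 1e-3))


def two_compartment_signal(
    m: PGSEMeasurement,
    p: MicrostructureParams,
    roots: BesselRootTable | None = None,
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
) -> float:
    """Normalized signal S/S0 = f_i S_i + (1 - f_i) S_e, in (0, 1]."""
    s_i = sphere_signal(m, p.R, p.D, roots, gamma)
    s_e = hindered_signal(m, p.D, p.f_i, gamma)
    return p.f_i * s_i + (1.0 - p.f_i) * s_e


def free_signal(b: float, D: float) -> float:
    """Mono-exponential free-diffusion signal exp(-b D); b in s/mm^2, D in um^2/ms."""
    if b < 0:
        raise ValueError(f"b must be non-negative, got {b}")
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    return float(np.exp(-b * D * 1e-3))


try:  # compiled hot path for the multistart fit and bootstrap refits
    from numba import njit

    @njit(cache=True)
    def _predict_kernel(R_m, f_i, D_si, D_um2ms, G_si, delta_s, Delta_s, b, x, gamma, out):
        K = G_si.shape[0]
        M = x.shape[0]
        R2 = R_m * R_m
        for k in range(K):
            d = delta_s[k]
            De = Delta_s[k]
            acc = 0.0
            for m in range(M):
                xm2 = x[m] * x[m]
                u = xm2 / R2 * D_si
                pref = R2 / (xm2 * (xm2 - 2.0))
                if u * d > 700.0:  # all exponentials underflow (very fast modes)
                    acc += pref * (2.0 * d / u - 2.0 / (u * u))
                else:
                    # e^{-u(De-d)} = E2/E1, e^{-u(De+d)} = E2*E1 (De >= d, so no overflow)
                    E1 = np.exp(-u * d)
                    E2 = np.exp(-u * De)
                    acc += pref * (
                        2.0 * d / u
                        + (-2.0 + 2.0 * E1 + 2.0 * E2 - E2 / E1 - E2 * E1) / (u * u)
                    )
            s_i = np.exp(-2.0 * gamma * gamma * G_si[k] * G_si[k] * acc)
            s_e = np.exp(-b[k] * (D_um2ms / (1.0 + f_i / 2.0)) * 1e-3)
            out[k] = f_i * s_i + (1.0 - f_i) * s_e

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class TwoCompartmentModel:
    """Vectorized two-compartment predictor bound to a fixed measurement set.

    Precomputes per-measurement SI arrays so repeated evaluation inside the
    multistart fit and the bootstrap refits is cheap; uses a JIT-compiled
    kernel when numba is importable, otherwise the numpy reference path.
    """

    def __init__(
        self,
        measurements: Protocol | list[PGSEMeasurement] | tuple[PGSEMeasurement, ...],
        gamma: float = GYROMAGNETIC_RATIO_PROTON,
        n_roots: int = 20,
        use_numba: bool = _HAVE_NUMBA,
    ):
        meas = list(measurements)
        self.measurements = tuple(meas)
        self.gamma = gamma
        self._G_si = np.array([m.G * 1e-3 for m in meas])
        self._delta_s = np.array([m.delta * 1e-3 for m in meas])
        self._Delta_s = np.array([m.Delta * 1e-3 for m in meas])
        self._b = np.array([m.b(gamma) for m in meas])     # s/mm^2
        self._x = bessel_roots(n_roots).roots
        self._use_numba = use_numba and _HAVE_NUMBA
        self._out = np.empty(len(meas))

    def predict(self, R: float, f_i: float, D: float) -> np.ndarray:
        """S/S0 for every bound measurement, given R (um), f_i, D (um^2/ms)."""
        if self._use_numba:
            _predict_kernel(
                R * 1e-6, f_i, D * 1e-9, D,
                self._G_si, self._delta_s, self._Delta_s, self._b, self._x,
                self.gamma, self._out,
            )
            return self._out.copy()
        return self._predict_numpy(R, f_i, D)

    def _predict_numpy(self, R: float, f_i: float, D: float) -> np.ndarray:
        """Reference numpy path (identical math; used for cross-checking)."""
        log_si = _gpd_log_attenuation(
            self._G_si, self._delta_s, self._Delta_s,
            R * 1e-6, D * 1e-9, self._x, self.gamma,
        )
        s_i = np.exp(log_si)
        s_e = np.exp(-self._b * (D / (1.0 + f_i / 2.0)) * 1e-3)
        return f_i * s_i + (1.0 - f_i) * s_e
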