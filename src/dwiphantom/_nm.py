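"""Compiled multistart Nelder-Mead for the two-compartment SSE objective.

The bootstrap refits evaluate the model objective millions of times; a plain
Python simplex loop dominates the runtime, so the whole multistart search is
JIT-compiled here: logistic box transform, SSE objective against the
precomputed measurement arrays, and a standard Nelder-Mead simplex
(reflection/expansion/contraction/shrink with the classic 1, 2, 1/2, 1/2
coefficients, scipy-style initial simplex, and the dual xatol/fatol
termination rule).  The scipy-based path in :mod:`dwiphantom.estimation`
remains available and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .signals import _predict_kernel

__all__ = ["fit_multistart_compiled"]


@njit(cache=True)
def _sse(z, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma, obs, out):
    # logistic transform onto the constraint box
    n = z.shape[0]
    p = np.empty(n)
    for i in range(n):
        p[i] = lo[i] + (hi[i] - lo[i]) / (1.0 + np.exp(-z[i]))
    R = p[0]
    f_i = p[1]
    D = D_fix if fix_D else p[2]
    _predict_kernel(R * 1e-6, f_i, D * 1e-9, D, G_si, delta_s, Delta_s, b, x, gamma, out)
    sse = 0.0
    for k in range(obs.shape[0]):
        r = out[k] - obs[k]
        sse += r * r
    return sse


@njit(cache=True)
def _sort_simplex(sim, fsim, n, tmp):
    # insertion sort over the n+1 vertices (n <= 3, so this is cheap)
    for i in range(1, n + 1):
        fi = fsim[i]
        for j in range(n):
            tmp[j] = sim[i, j]
        k = i - 1
        while k >= 0 and fsim[k] > fi:
            fsim[k + 1] = fsim[k]
            for j in range(n):
                sim[k + 1, j] = sim[k, j]
            k -= 1
        fsim[k + 1] = fi
        for j in range(n):
            sim[k + 1, j] = tmp[j]


@njit(cache=True)
def _nelder_mead(z0, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma,
                 obs, out, xatol, fatol, maxiter):
    n = z0.shape[0]
    # scipy-style initial simplex
    sim = np.empty((n + 1, n))
    fsim = np.empty(n + 1)
    xbar = np.empty(n)
    cand = np.empty(n)
    tmp = np.empty(n)
    for j in range(n):
        sim[0, j] = z0[j]
    for k in range(n):
        for j in range(n):
            sim[k + 1, j] = z0[j]
        sim[k + 1, k] = 1.05 * z0[k] if z0[k] != 0.0 else 0.00025
    for i in range(n + 1):
        fsim[i] = _sse(sim[i], lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x,
                       gamma, obs, out)
    _sort_simplex(sim, fsim, n, tmp)

    rho, chi, psi, sigma = 1.0, 2.0, 0.5, 0.5
    it = 0
    while it < maxiter:
        # termination: simplex position spread and objective spread
        max_x = 0.0
        max_f = 0.0
        for i in range(1, n + 1):
            for j in range(n):
                d = abs(sim[i, j] - sim[0, j])
                if d > max_x:
                    max_x = d
            df = abs(fsim[i] - fsim[0])
            if df > max_f:
                max_f = df
        if max_x <= xatol and max_f <= fatol:
            break
        # centroid of the best n vertices
        for j in range(n):
            acc = 0.0
            for i in range(n):
                acc += sim[i, j]
            xbar[j] = acc / n
        for j in range(n):
            cand[j] = (1.0 + rho) * xbar[j] - rho * sim[n, j]
        fxr = _sse(cand, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma, obs, out)
        shrink = False
        if fxr < fsim[0]:
            for j in range(n):
                tmp[j] = cand[j]  # keep xr
            for j in range(n):
                cand[j] = (1.0 + rho * chi) * xbar[j] - rho * chi * sim[n, j]
            fxe = _sse(cand, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma, obs, out)
            if fxe < fxr:
                for j in range(n):
                    sim[n, j] = cand[j]
                fsim[n] = fxe
            else:
                for j in range(n):
                    sim[n, j] = tmp[j]
                fsim[n] = fxr
        elif fxr < fsim[n - 1]:
            for j in range(n):
                sim[n, j] = cand[j]
            fsim[n] = fxr
        else:
            if fxr < fsim[n]:
                fxr_keep = fxr
                for j in range(n):
                    tmp[j] = cand[j]
                for j in range(n):
                    cand[j] = (1.0 + psi * rho) * xbar[j] - psi * rho * sim[n, j]
                fxc = _sse(cand, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma, obs, out)
                if fxc <= fxr_keep:
                    for j in range(n):
                        sim[n, j] = cand[j]
                    fsim[n] = fxc
                else:
                    shrink = True
            else:
                for j in range(n):
                    cand[j] = (1.0 - psi) * xbar[j] + psi * sim[n, j]
                fxcc = _sse(cand, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma, obs, out)
                if fxcc < fsim[n]:
                    for j in range(n):
                        sim[n, j] = cand[j]
                    fsim[n] = fxcc
                else:
                    shrink = True
            if shrink:
                for i in range(1, n + 1):
                    for j in range(n):
                        sim[i, j] = sim[0, j] + sigma * (sim[i, j] - sim[0, j])
                    fsim[i] = _sse(sim[i], lo, hi, fix_D, D_fix, G_si, delta_s,
                                   Delta_s, b, x, gamma, obs, out)
        _sort_simplex(sim, fsim, n, tmp)
        it += 1
    return sim[0], fsim[0]


@njit(cache=True)
def _multistart(starts, lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s, b, x, gamma,
                obs, xatol, fatol, maxiter):
    n = starts.shape[1]
    out = np.empty(obs.shape[0])
    best_z = np.empty(n)
    best_f = np.inf
    for s in range(starts.shape[0]):
        z, f = _nelder_mead(starts[s], lo, hi, fix_D, D_fix, G_si, delta_s, Delta_s,
                            b, x, gamma, obs, out, xatol, fatol, maxiter)
        if f < best_f:
            best_f = f
            best_z = z.copy()
    return best_z, best_f


def fit_multistart_compiled(
    starts_z: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    fixed_D: float | None,
    model,
    obs: np.ndarray,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
    maxiter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Best (z, SSE) over Nelder-Mead runs from each row of ``starts_z``.

    ``model`` is a :class:`~dwiphantom.signals.TwoCompartmentModel`; ``lo``/
    ``hi`` bound the free parameters ((R, f_i) when ``fixed_D`` is given,
    else (R, f_i, D)); ``starts_z`` holds unconstrained (logit-space) starts.
    """
    fix = fixed_D is not None
    return _multistart(
        np.ascontiguousarray(starts_z, dtype=np.float64),
        np.ascontiguousarray(lo, dtype=np.float64),
        np.ascontiguousarray(hi, dtype=np.float64),
        fix,
        float(fixed_D) if fix else 0.0,
        model._G_si, model._delta_s, model._Delta_s, model._b, model._x,
        model.gamma,
        np.ascontiguousarray(obs, dtype=np.float64),
        xatol, fatol, maxiter,
    )
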