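"""Monte-Carlo random-walk oracle for PGSE signals.

Walkers perform Gaussian steps (per-axis SD sqrt(2 D dt)); the sphere substrate
reflects steps specularly at the boundary (mirror about the tangent plane at
the crossing point, iterated for multiple reflections).  Spin phase is accrued
literally through the finite-duration rectangular gradient waveform,

    phi = gamma * sum_k g(t_k) x(t_k) dt,   g = +G on [0, delta), -G on [Delta, Delta+delta),

so the simulation probes the full GPD expression, not the narrow-pulse limit.
The signal estimate is |mean_w exp(i phi_w)| with a delta-method standard error.

This module is the independent numerical check for the analytic sphere model:
it shares no code with the GPD series.  The walk is vectorized across walkers;
all randomness flows from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import GYROMAGNETIC_RATIO_PROTON, PGSEMeasurement

__all__ = ["RandomWalkConfig", "mc_pgse_signal"]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Configuration for the random-walk simulation.

    ``dt`` (ms) defaults to the largest value satisfying the discretization
    rule sqrt(6 D dt) <= R/20 for the sphere substrate (snapped down to 1/n ms
    so pulse edges fall on the step grid for integer-ms timings); steps longer
    than R/10 are rejected outright.
    """

    n_walkers: int = 100_000
    D: float = 2.0                  # um^2/ms
    substrate: str = "free"         # "free" or "sphere"
    R: float | None = None          # um, sphere substrate only
    dt: float | None = None         # ms
    seed: int = 0
    boundary: str = "reflect"       # "reflect" (specular) or "reject"

    def __post_init__(self) -> None:
        if self.n_walkers < 1_000:
            raise ValueError(f"need at least 1000 walkers, got {self.n_walkers}")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.substrate not in ("free", "sphere"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.boundary not in ("reflect", "reject"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")
        if self.substrate == "sphere":
            if self.R is None or self.R <= 0:
                raise ValueError("sphere substrate needs a positive radius R")
            step = math.sqrt(6.0 * self.D * self.resolved_dt())
            if step > self.R / 10.0:
                raise ValueError(f"step length {step:.3g} um exceeds R/10; decrease dt")

    def resolved_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        if self.substrate == "sphere":
            # sqrt(6 D dt) = R/20  =>  dt = R^2 / (2400 D); snap to 1/n ms
            dt_max = self.R**2 / (2400.0 * self.D)
            return 1.0 / math.ceil(1.0 / dt_max)
        return 0.01  # ms; free diffusion is exact at any dt, this sets waveform resolution


def _reflect_subset(p: np.ndarray, n: np.ndarray, R: float) -> np.ndarray:
    """Specular reflection for walkers that left the sphere in one step.

    ``p`` holds the pre-step positions (inside the sphere), ``n`` the
    candidate end points (outside).  The remaining path is mirrored about the
    tangent plane at the boundary crossing; multiple reflections per step are
    handled by iterating, with a final round-off clamp that is essentially
    never reached.
    """
    R2 = R * R
    p = p.copy()
    n = n.copy()
    out = np.arange(len(n))
    for _ in range(16):
        po, no = p[out], n[out]
        e = no - po
        a = np.einsum("ij,ij->i", e, e)
        b = 2.0 * np.einsum("ij,ij->i", po, e)
        c = np.einsum("ij,ij->i", po, po) - R2
        disc = np.maximum(b * b - 4.0 * a * c, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (-b + np.sqrt(disc)) / (2.0 * a)
        t = np.clip(np.nan_to_num(t), 0.0, 1.0)[:, None]
        q = po + t * e                      # boundary crossing point
        u = q / R                           # outward unit normal
        r = no - q                          # remaining path
        dot = np.einsum("ij,ij->i", r, u)[:, None]
        n[out] = q + r - 2.0 * dot * u
        p[out] = q
        still = np.einsum("ij,ij->i", n[out], n[out]) > R2
        if not np.any(still):
            return n
        out = out[still]
    r = np.sqrt(np.einsum("ij,ij->i", n[out], n[out]))[:, None]
    n[out] = n[out] * (R * (1.0 - 1e-6) / r)
    return n


def mc_pgse_signal(
    cfg: RandomWalkConfig,
    m: PGSEMeasurement,
    gamma: float = GYROMAGNETIC_RATIO_PROTON,
) -> tuple[float, float]:
    """Monte-Carlo PGSE signal estimate and its standard error.

    Returns ``(signal, SE)``; the signal is the magnitude of the
    ensemble-averaged phase factor.  G = 0 returns (1, 0) exactly.
    """
    if m.G == 0:
        return 1.0, 0.0
    dt = cfg.resolved_dt()
    T = m.Delta + m.delta                          # ms
    n_steps = max(1, int(math.ceil(T / dt - 1e-9)))
    # rectangular waveform sampled at step midpoints, in T/m
    t_mid = (np.arange(n_steps) + 0.5) * dt
    g_wave = np.zeros(n_steps)
    g_wave[t_mid < m.delta] = m.G * 1e-3
    g_wave[(t_mid >= m.Delta) & (t_mid < m.Delta + m.delta)] = -m.G * 1e-3
    dt_s = dt * 1e-3
    D_si = cfg.D * 1e-9                            # m^2/s
    step_sd = math.sqrt(2.0 * D_si * dt_s)         # m, per axis
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_walkers
    phases = np.zeros(N)

    if cfg.substrate == "free":
        # only the gradient axis matters for free diffusion
        x = np.zeros(N)
        for k in range(n_steps):
            x += step_sd * rng.standard_normal(N)
            g = g_wave[k]
            if g != 0.0:
                phases += (gamma * g * dt_s) * x
    else:
        # Positions are held in um as float32: values are O(R) so the relative
        # round-off (~6e-8) is ~1e-6 um, far below the step length; phases are
        # accumulated in float64.
        R_um = float(cfg.R)
        if math.sqrt(6.0 * cfg.D * dt) > R_um / 10.0:
            raise ValueError("step length exceeds R/10; decrease dt")
        step_sd_um = np.float32(math.sqrt(2.0 * cfg.D * dt))
        # uniform start inside the sphere (radius ~ cbrt(uniform))
        u = rng.random(N)
        dirs = rng.standard_normal((N, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = (dirs * (R_um * np.cbrt(u))[:, None]).astype(np.float32)
        reject = cfg.boundary == "reject"
        R2 = np.float32(R_um * R_um)
        for k in range(n_steps):
            cand = pos + step_sd_um * rng.standard_normal((N, 3), dtype=np.float32)
            r2 = np.einsum("ij,ij->i", cand, cand)
            out = np.nonzero(r2 > R2)[0]
            if out.size:
                if reject:
                    cand[out] = pos[out]        # rejected step: walker stays put
                else:
                    cand[out] = _reflect_subset(pos[out], cand[out], R_um)
            pos = cand
            g = g_wave[k]
            if g != 0.0:
                # x in um -> m for the phase integral
                phases += (gamma * g * dt_s * 1e-6) * pos[:, 0].astype(np.float64)
        assert np.all(
            np.einsum("ij,ij->i", pos.astype(np.float64), pos.astype(np.float64))
            <= float(R2) * (1 + 1e-5)
        ), "walker escaped the sphere"

    return _signal_from_phases(phases)


def _signal_from_phases(phases: np.ndarray) -> tuple[float, float]:
    """(|mean exp(i phi)|, delta-method SE) from walker phases."""
    c = np.cos(phases)
    s = np.sin(phases)
    n = len(phases)
    mc, ms = c.mean(), s.mean()
    sig = math.hypot(mc, ms)
    if sig == 0.0:
        return 0.0, float(np.sqrt((c.var() + s.var()) / n))
    gc, gs = mc / sig, ms / sig
    cov = np.cov(c, s) / n
    var = gc * gc * cov[0, 0] + 2 * gc * gs * cov[0, 1] + gs * gs * cov[1, 1]
    return float(sig), float(math.sqrt(max(var, 0.0)))
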