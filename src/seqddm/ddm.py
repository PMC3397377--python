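"""Closed-form first-passage statistics of the pure drift-diffusion model.

The pure DDM accumulates evidence ``dx = mu dt + sigma dW`` from an initial
condition ``x0`` until absorption at the thresholds ``+-z`` (``+z`` is the
correct boundary; ``mu > 0`` by convention points toward it).  All statistics
are expressed in the scaled parameterization

    z_tilde  = z  / mu   (seconds)
    x0_tilde = x0 / mu   (seconds)
    mu_tilde = (mu / sigma)**2   (1 / seconds)

under which the error rate and the mean decision times — unconditional and
conditional on correctness — have closed forms.  A brute-force Euler–Maruyama
simulator of the unscaled process is provided as an independent numerical
oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _fast


@dataclass(frozen=True)
class ScaledDDMParams:
    """One trial's scaled diffusion parameters.

    mu_tilde : scaled drift (signal-to-noise rate), 1/seconds, > 0
    z_tilde  : scaled threshold, seconds, > 0
    x0_tilde : scaled initial condition, seconds, |x0_tilde| < z_tilde
    t_nd     : non-decision time, seconds, >= 0
    """

    mu_tilde: float
    z_tilde: float
    x0_tilde: float = 0.0
    t_nd: float = 0.0

    def __post_init__(self):
        if not self.mu_tilde > 0:
            raise ValueError(f"mu_tilde must be > 0, got {self.mu_tilde}")
        if not self.z_tilde > 0:
            raise ValueError(f"z_tilde must be > 0, got {self.z_tilde}")
        if not abs(self.x0_tilde) < self.z_tilde:
            raise ValueError(
                f"|x0_tilde| must be < z_tilde, got x0_tilde={self.x0_tilde}, "
                f"z_tilde={self.z_tilde}"
            )
        if self.t_nd < 0:
            raise ValueError(f"t_nd must be >= 0, got {self.t_nd}")


@dataclass(frozen=True)
class FirstPassageStats:
    """Error probability and mean decision times (seconds) of one diffusion.

    ``dt_correct`` / ``dt_error`` are NaN when the conditioning event has
    probability zero.  Satisfies (1 - er) * dt_correct + er * dt_error =
    dt_mean whenever both conditional means are defined.
    """

    er: float
    dt_mean: float
    dt_correct: float
    dt_error: float


@dataclass(frozen=True)
class MCFirstPassageStats:
    """Empirical first-passage statistics with Monte-Carlo standard errors."""

    er: float
    dt_mean: float
    dt_correct: float
    dt_error: float
    er_se: float
    dt_mean_se: float
    dt_correct_se: float
    dt_error_se: float
    n_paths: int
    n_unabsorbed: int


def scale_parameters(mu: float, sigma: float, z: float, x0: float = 0.0,
                     t_nd: float = 0.0) -> ScaledDDMParams:
    """Map unscaled diffusion parameters to the scaled parameterization.

    Requires mu > 0, sigma > 0, z > 0 and |x0| < z.
    """
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not z > 0:
        raise ValueError(f"z must be > 0, got {z}")
    if not abs(x0) < z:
        raise ValueError(f"|x0| must be < z, got x0={x0}, z={z}")
    return ScaledDDMParams(
        mu_tilde=(mu / sigma) ** 2,
        z_tilde=z / mu,
        x0_tilde=x0 / mu,
        t_nd=t_nd,
    )


def error_rate(p: ScaledDDMParams) -> float:
    """Probability of absorption at the error boundary, in [0, 1]."""
    return float(_fast.er_ufunc(p.mu_tilde, p.z_tilde, p.x0_tilde))


def mean_decision_time(p: ScaledDDMParams) -> float:
    """Mean decision time in seconds (non-decision time not included)."""
    return float(_fast.dt_mean_ufunc(p.mu_tilde, p.z_tilde, p.x0_tilde))


def conditional_mean_dts(p: ScaledDDMParams) -> tuple[float, float]:
    """Mean decision times on correct and on error trials, in seconds.

    Returns ``(dt_correct, dt_error)``; a component is NaN when ER is exactly
    1 (no correct trials) or 0 (no error trials), respectively.
    """
    dtc = float(_fast.dt_correct_ufunc(p.mu_tilde, p.z_tilde, p.x0_tilde))
    dte = float(_fast.dt_error_ufunc(p.mu_tilde, p.z_tilde, p.x0_tilde))
    return dtc, dte


def first_passage_stats(p: ScaledDDMParams) -> FirstPassageStats:
    """All four closed-form statistics for one parameter set."""
    dtc, dte = conditional_mean_dts(p)
    return FirstPassageStats(
        er=error_rate(p),
        dt_mean=mean_decision_time(p),
        dt_correct=dtc,
        dt_error=dte,
    )


def first_passage_grid(mu_tilde, z_tilde, x0_tilde):
    """Vectorized ER / mean DT / conditional DTs over broadcastable arrays.

    Returns a dict of arrays ``{"er", "dt_mean", "dt_correct", "dt_error"}``.
    Intended for parameter sweeps and property checks.
    """
    th = np.asarray(mu_tilde, dtype=float)
    a = np.asarray(z_tilde, dtype=float)
    x = np.asarray(x0_tilde, dtype=float)
    # the SIMD-compiled conditional-mean loop may speculatively evaluate the
    # guarded division on lanes where ER is exactly 0/1; results are correct
    # (NaN is substituted), so the transient FP flags are suppressed
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "er": _fast.er_ufunc(th, a, x),
            "dt_mean": _fast.dt_mean_ufunc(th, a, x),
            "dt_correct": _fast.dt_correct_ufunc(th, a, x),
            "dt_error": _fast.dt_error_ufunc(th, a, x),
        }


def mc_first_passage_oracle(mu: float, sigma: float, z: float, x0: float,
                            step: float | None = None, n_paths: int = 200_000,
                            seed: int | None = None,
                            horizon: float | None = None,
                            bridge: bool = True) -> MCFirstPassageStats:
    """Euler–Maruyama first-passage simulation of the unscaled diffusion.

    Simulates ``n_paths`` paths of dx = mu dt + sigma dW from x0, absorbed at
    +-z, with time step ``step`` (seconds).  ``step`` must be small relative
    to the characteristic passage time min(z/mu, z**2/sigma**2); the default
    (``step=None``) takes 1/500 of that scale, capped at 1e-4 s.  With
    ``bridge=True`` (default) a Brownian-bridge test detects within-step
    boundary touches, removing the O(sqrt(step)) absorption bias of naive
    Euler discretization.

    Paths not absorbed by ``horizon`` (default 200 * z/mu seconds) are counted
    in ``n_unabsorbed`` and excluded from the means; a warning is emitted if
    they exceed 0.1% of paths.  Deterministic given ``seed``.
    """
    if x0 >= z:
        # started on (or beyond) the correct boundary: immediate absorption
        return MCFirstPassageStats(0.0, 0.0, 0.0, math.nan, 0.0, 0.0, 0.0,
                                   math.nan, n_paths, 0)
    if x0 <= -z:
        return MCFirstPassageStats(1.0, 0.0, math.nan, 0.0, 0.0, 0.0,
                                   math.nan, 0.0, n_paths, 0)
    if n_paths < 2:
        raise ValueError("n_paths must be >= 2")
    if step is None:
        t_char = z * z / (sigma * sigma)
        if mu > 0:
            t_char = min(t_char, z / mu)
        step = min(1e-4, t_char / 500.0)
    if horizon is None:
        if mu <= 0:
            raise ValueError("horizon must be given explicitly when mu <= 0")
        horizon = 200.0 * z / mu
    max_steps = int(math.ceil(horizon / step))

    kernel_seed = (0 if seed is None
                   else int(np.random.SeedSequence(seed).generate_state(1)[0]
                            % (2 ** 31)))
    side, steps = _fast.mc_core(float(mu), float(sigma), float(z), float(x0),
                                float(step), int(n_paths), max_steps,
                                kernel_seed, bridge)

    n_unabsorbed = int((side == 0).sum())
    if n_unabsorbed > 0.001 * n_paths:
        warnings.warn(
            f"{n_unabsorbed} of {n_paths} paths not absorbed within the "
            f"{horizon:g} s horizon; first-passage estimates are truncated",
            RuntimeWarning,
            stacklevel=2,
        )

    times = steps * step
    tc = times[side == 1]
    te = times[side == -1]
    n_done = tc.size + te.size
    er = te.size / n_done if n_done else math.nan
    t_all = np.concatenate([tc, te]) if n_done else np.empty(0)

    def _mean_se(arr):
        if arr.size == 0:
            return math.nan, math.nan
        if arr.size == 1:
            return float(arr[0]), math.nan
        return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))

    dt_mean, dt_mean_se = _mean_se(t_all)
    dt_c, dt_c_se = _mean_se(tc)
    dt_e, dt_e_se = _mean_se(te)
    er_se = math.sqrt(er * (1.0 - er) / n_done) if n_done else math.nan
    return MCFirstPassageStats(
        er=er, dt_mean=dt_mean, dt_correct=dt_c, dt_error=dt_e,
        er_se=er_se, dt_mean_se=dt_mean_se, dt_correct_se=dt_c_se,
        dt_error_se=dt_e_se, n_paths=n_paths, n_unabsorbed=n_unabsorbed,
    )
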