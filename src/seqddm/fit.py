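"""Least-squares fitting of the adaptive model to summary vectors.

The objective is the unweighted sum of squared differences between the model
and data condition summary vectors (RTs in seconds, ERs in decimal
fractions, so element magnitudes are comparable).  Per evaluation the model
is run at least five times through the *same* stimulus sequences the data
table contains, the simulated trials are sorted and summarized exactly like
the data, and elements undefined in either vector are dropped pairwise.

Common random numbers (a fixed seed per evaluation) make the stochastic
objective quasi-deterministic, which finite-difference trust-region solvers
require.  Minimization uses scipy's trust-region-reflective bounded least
squares.  Model scores use the Gaussian-residual least-squares forms of
AIC / AICc / BIC with n = the number of compared summary elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import analysis
from .mechanisms import (AdaptiveModelParams, prepare_session,
                         run_prepared_session)

#: penalty residual (seconds / fraction units) for a summary element defined
#: in the data but empty in the model simulation
_MISSING_PENALTY = 1.0

_PARAM_NAMES = ("mu_tilde", "t_nd", "k", "x_offset", "delta",
                "z_down", "z_up", "z_max")

#: internal optimizer coordinates: z_max is carried as the slack above its
#: floor k/2 + x_offset so box bounds cannot produce an empty threshold range
_COORD_NAMES = ("mu_tilde", "t_nd", "k", "x_offset", "delta",
                "z_down", "z_up", "z_slack")

DEFAULT_BOUNDS = {
    "mu_tilde": (1.0, 80.0),
    "t_nd": (0.05, 0.60),
    "k": (1e-4, 0.5),
    "x_offset": (1e-5, 0.05),
    "delta": (0.01, 0.99),
    "z_down": (1e-5, 0.10),
    "z_up": (1e-5, 0.50),
    "z_slack": (1e-3, 0.94),
}

#: central start point used as the first multi-start candidate
DEFAULT_START = {
    "mu_tilde": 25.0, "t_nd": 0.30, "k": 0.10, "x_offset": 0.005,
    "delta": 0.60, "z_down": 0.005, "z_up": 0.10, "z_slack": 0.15,
}

_X_SCALE = np.array([20.0, 0.3, 0.1, 0.01, 0.5, 0.01, 0.1, 0.1])


def params_to_coords(params: AdaptiveModelParams) -> np.ndarray:
    x = [params.mu_tilde, params.t_nd, params.k, params.x_offset,
         params.delta, params.z_down, params.z_up,
         params.z_max - params.z_floor]
    return np.asarray(x, dtype=float)


def coords_to_params(x: np.ndarray) -> AdaptiveModelParams:
    mu, t_nd, k, x_off, delta, z_down, z_up, z_slack = x
    return AdaptiveModelParams(
        mu_tilde=mu, t_nd=t_nd, k=k, x_offset=x_off, delta=delta,
        z_down=z_down, z_up=z_up, z_max=0.5 * k + x_off + max(z_slack, 0.0),
    )


class InfoCriteria(NamedTuple):
    aic: float
    aicc: float  # NaN when n - p - 1 <= 0
    bic: float


def information_criteria(err: float, n: int, p: int) -> InfoCriteria:
    """Least-squares information criteria from a residual sum of squares.

    ``aic = n ln(err/n) + 2p``; ``aicc`` adds the small-sample correction
    ``2p(p+1)/(n-p-1)`` and is NaN when ``n - p - 1 <= 0`` (too few compared
    means relative to parameters); ``bic = n ln(err/n) + p ln(n)``.  A zero
    residual yields -inf scores.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if err < 0:
        raise ValueError(f"err must be >= 0, got {err}")
    if err == 0:
        aic = bic = -math.inf
        aicc = -math.inf if n - p - 1 > 0 else math.nan
        return InfoCriteria(aic, aicc, bic)
    base = n * math.log(err / n)
    aic = base + 2 * p
    aicc = aic + 2 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else math.nan
    bic = base + p * math.log(n)
    return InfoCriteria(aic, aicc, bic)


# ---------------------------------------------------------------------------
# fast summary path (numpy only, used inside the objective)
# ---------------------------------------------------------------------------

_CODE_OF_LABEL = {"RR": 3, "AR": 1, "RA": 2, "AA": 0}
_CODES = np.array([_CODE_OF_LABEL[lab] for lab in analysis.LABELS])


def _condition_vector(trans, correct, rt, run_id, mask, lo, hi):
    """19-element summary for the trials selected by ``mask``."""
    outlier = (rt < lo) | (rt > hi)
    prev_same_run = np.zeros(trans.shape[0], dtype=bool)
    prev_same_run[1:] = run_id[1:] == run_id[:-1]
    seq_ok = np.zeros(trans.shape[0], dtype=bool)
    seq_ok[1:] = (trans[1:] >= 0) & (trans[:-1] >= 0) & prev_same_run[1:]

    vec = np.full(19, np.nan)
    sel = seq_ok & ~outlier & mask
    if sel.any():
        code = np.zeros(trans.shape[0], dtype=np.int64)
        code[1:] = 2 * trans[:-1] + np.maximum(trans[1:], 0)
        c = code[sel]
        r = rt[sel]
        corr = correct[sel].astype(bool)
        n_tot = np.bincount(c, minlength=4).astype(float)
        s_tot = np.bincount(c, weights=r, minlength=4)
        n_cor = np.bincount(c[corr], minlength=4).astype(float)
        s_cor = np.bincount(c[corr], weights=r[corr], minlength=4)
        n_err = n_tot - n_cor
        s_err = s_tot - s_cor
        with np.errstate(invalid="ignore", divide="ignore"):
            rt_all = np.where(n_tot > 0, s_tot / n_tot, np.nan)[_CODES]
            rt_cor = np.where(n_cor > 0, s_cor / n_cor, np.nan)[_CODES]
            rt_err = np.where(n_err > 0, s_err / n_err, np.nan)[_CODES]
            er = np.where(n_tot > 0, n_err / n_tot, np.nan)[_CODES]
        vec[0:4] = rt_all
        vec[4:8] = rt_cor
        vec[8:12] = rt_err
        vec[12:16] = er

    # error triplets: anchors are error trials with both neighbors in-run
    n = trans.shape[0]
    err_pos = np.flatnonzero((correct == 0) & mask)
    err_pos = err_pos[(err_pos >= 1) & (err_pos <= n - 2)]
    if err_pos.size:
        in_run = (run_id[err_pos - 1] == run_id[err_pos]) & \
                 (run_id[err_pos + 1] == run_id[err_pos])
        err_pos = err_pos[in_run]
    for j, off in enumerate((-1, 0, 1)):
        if err_pos.size:
            entries = rt[err_pos + off][~outlier[err_pos + off]]
            if entries.size:
                vec[16 + j] = entries.mean()
    return vec


def fast_summary_vector(sim: dict, by_condition: bool,
                        lo: float = analysis.OUTLIER_LO,
                        hi: float = analysis.OUTLIER_HI) -> np.ndarray:
    """Summary vector from ``simulate_session(..., as_frame=False)`` output.

    Numerically identical to the pandas pipeline in :mod:`seqddm.analysis`
    (asserted in the test suite) but ~two orders of magnitude faster, which
    the fitting objective needs.
    """
    trans = sim["transition"].astype(np.int64)
    correct = sim["correct"].astype(np.uint8)
    rt = sim["rt"]
    run_id = sim["run_id"]
    if not by_condition:
        mask = np.ones(trans.shape[0], dtype=bool)
        return _condition_vector(trans, correct, rt, run_id, mask, lo, hi)
    p_alt = sim["p_alt"]
    parts = []
    for p in np.unique(p_alt[~np.isnan(p_alt)]):
        parts.append(_condition_vector(trans, correct, rt, run_id,
                                       p_alt == p, lo, hi))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# objective and optimizer
# ---------------------------------------------------------------------------

def model_summary_vector(params: AdaptiveModelParams,
                         stimulus_blocks: Sequence[np.ndarray] | None = None,
                         p_alts=None, n_passes: int = 5,
                         seed: int = 0,
                         lo: float = analysis.OUTLIER_LO,
                         hi: float = analysis.OUTLIER_HI,
                         prep: dict | None = None) -> np.ndarray:
    """Simulate the model on the given stimuli and summarize (fast path).

    ``prep`` (from :func:`seqddm.mechanisms.prepare_session`) bypasses the
    per-call RNG stream setup; the optimizer reuses one prepared session for
    every objective evaluation (common random numbers).
    """
    if prep is None:
        if stimulus_blocks is None:
            raise ValueError("either stimulus_blocks or prep is required")
        prep = prepare_session(stimulus_blocks, n_passes=n_passes, seed=seed,
                               p_alt=p_alts)
    by_condition = (np.unique(prep["p_alt"][~np.isnan(prep["p_alt"])]).size
                    > 1)
    sim = run_prepared_session(prep, params)
    return fast_summary_vector(sim, by_condition, lo, hi)


def _residuals(model_vec: np.ndarray, data_vec: np.ndarray) -> np.ndarray:
    data_ok = np.isfinite(data_vec)
    if not data_ok.any():
        raise ValueError("data summary vector has no defined elements")
    diff = model_vec[data_ok] - data_vec[data_ok]
    diff[~np.isfinite(diff)] = _MISSING_PENALTY
    return diff


def objective(params: AdaptiveModelParams, data_vector,
              stimulus_blocks: Sequence[np.ndarray], p_alts=None,
              n_passes: int = 5, seed: int = 0) -> float:
    """Sum-of-squares discrepancy between model and data summary vectors.

    ``data_vector`` may be the pandas Series from
    :func:`seqddm.analysis.summary_vector` or a plain array in canonical
    element order.  Elements undefined (NaN) in the data are dropped; an
    element defined in the data but empty in the model contributes a fixed
    penalty.  Deterministic given ``seed``.
    """
    data_vec = np.asarray(data_vector, dtype=float)
    model_vec = model_summary_vector(params, stimulus_blocks, p_alts,
                                     n_passes=n_passes, seed=seed)
    if model_vec.shape != data_vec.shape:
        raise ValueError(
            f"model and data vectors differ in length "
            f"({model_vec.shape[0]} vs {data_vec.shape[0]}); check the "
            f"condition set"
        )
    r = _residuals(model_vec, data_vec)
    return float(np.dot(r, r))


@dataclass
class FitResult:
    """Outcome of one model fit."""

    params: AdaptiveModelParams
    err: float
    n_elements: int
    n_params: int
    aic: float
    aicc: float
    bic: float
    converged: bool
    message: str
    seed: int
    n_passes: int
    n_starts: int
    start_errs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {name: getattr(self.params, name) for name in _PARAM_NAMES}
        return {
            "params": d,
            "err": self.err,
            "n_elements": self.n_elements,
            "n_params": self.n_params,
            "aic": self.aic,
            "aicc": self.aicc,
            "bic": self.bic,
            "converged": self.converged,
            "message": self.message,
            "seed": self.seed,
            "n_passes": self.n_passes,
            "n_starts": self.n_starts,
            "start_errs": list(self.start_errs),
        }


def extract_stimulus_blocks(data_table: pd.DataFrame):
    """Stimulus sequences and block p_alt values from a single-pass table."""
    keys = [c for c in ("subject", "pass", "block") if c in data_table.columns]
    stimuli, p_alts = [], []
    for _, g in data_table.groupby(keys, sort=False):
        stimuli.append(g.sort_values("trial")["stimulus"].to_numpy())
        p_alts.append(float(g["p_alt"].iloc[0])
                      if "p_alt" in g.columns else np.nan)
    return stimuli, p_alts


def _draw_start(rng: np.random.Generator) -> np.ndarray:
    """Log-uniform start draw within the default bounds."""
    x = np.empty(len(_COORD_NAMES))
    for i, name in enumerate(_COORD_NAMES):
        lo, hi = DEFAULT_BOUNDS[name]
        if name == "delta":
            x[i] = rng.uniform(0.2, 0.9)
        else:
            x[i] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return x


def fit_model(data_table: pd.DataFrame, n_passes: int = 10, seed: int = 0,
              n_starts: int = 4, bounds: dict | None = None,
              start: AdaptiveModelParams | None = None,
              max_nfev: int | None = 400,
              diff_step: float = 1e-2,
              fixed: dict | None = None) -> FitResult:
    """Fit the eight-parameter adaptive model to one trial table.

    The model is simulated on the same per-block stimulus sequences as the
    data (``n_passes`` passes, common random numbers fixed by ``seed``) and
    the summary-vector sum of squares is minimized with bounded
    trust-region-reflective least squares from ``n_starts`` start points
    (the central default / supplied ``start``, then seeded log-uniform
    draws).  ``fixed`` pins named parameters (in optimizer coordinates,
    ``z_slack`` standing in for ``z_max``) at given values, reducing the
    effective parameter count in the information criteria.

    Non-convergence is reported through ``converged`` / ``message``, never
    raised.
    """
    labeled = analysis.label_transitions_and_sequences(data_table)
    labeled = analysis.flag_outliers(labeled)
    by_condition = ("p_alt" in labeled.columns
                    and labeled["p_alt"].dropna().nunique() > 1)
    data_vec = analysis.summary_vector(labeled, by_condition=by_condition)\
        .to_numpy()
    stimuli, p_alts = extract_stimulus_blocks(data_table)
    if not by_condition:
        p_alts = None

    prep = prepare_session(stimuli, n_passes=n_passes, seed=seed,
                           p_alt=p_alts)

    fixed = dict(fixed or {})
    for name in fixed:
        if name not in _COORD_NAMES:
            raise ValueError(f"unknown fixed parameter {name!r}")
    free_idx = [i for i, n in enumerate(_COORD_NAMES) if n not in fixed]
    if not free_idx:
        raise ValueError("at least one parameter must be free")

    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo_b = np.array([bnds[n][0] for n in _COORD_NAMES])
    hi_b = np.array([bnds[n][1] for n in _COORD_NAMES])
    full0 = params_to_coords(start) if start is not None else \
        np.array([DEFAULT_START[n] for n in _COORD_NAMES])
    full0 = np.clip(full0, lo_b, hi_b)
    for name, val in fixed.items():
        full0[_COORD_NAMES.index(name)] = val

    data_ok = np.isfinite(data_vec)
    n_elements = int(data_ok.sum())
    n_free = len(free_idx)

    def embed(xfree):
        full = full0.copy()
        full[free_idx] = xfree
        return full

    def resid(xfree):
        params = coords_to_params(embed(xfree))
        model_vec = model_summary_vector(params, prep=prep)
        return _residuals(model_vec, data_vec)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17]))

    # coarse pre-screen: the objective is cheap, so score a pool of random
    # candidates and polish only the best ones
    def quick_err(x_full):
        r = _residuals(model_summary_vector(coords_to_params(x_full),
                                            prep=prep), data_vec)
        return float(np.dot(r, r))

    pool = [full0]
    for _ in range(max(8 * n_starts, 24)):
        cand = np.clip(_draw_start(rng), lo_b, hi_b)
        for name, val in fixed.items():
            cand[_COORD_NAMES.index(name)] = val
        pool.append(cand)
    pool_scores = [quick_err(c) for c in pool]
    order = np.argsort(pool_scores)
    starts = [pool[0]] + [pool[i] for i in order if i != 0]
    starts = starts[:n_starts]

    best = None
    start_errs = []
    for x0_full in starts:
        x0 = x0_full[free_idx]
        try:
            res = least_squares(
                resid, x0, bounds=(lo_b[free_idx], hi_b[free_idx]),
                method="trf", x_scale=_X_SCALE[free_idx],
                diff_step=diff_step, max_nfev=max_nfev,
            )
            err = float(2 * res.cost)
            start_errs.append(err)
            if best is None or err < best[0]:
                best = (err, res)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            start_errs.append(math.nan)
            if best is None:
                best = (math.inf, exc)

    err, res = best
    if isinstance(res, Exception):
        params = coords_to_params(full0)
        converged, message = False, f"optimization failed: {res}"
        err = objective(params, data_vec, stimuli, p_alts,
                        n_passes=n_passes, seed=seed)
    else:
        params = coords_to_params(embed(res.x))
        converged = bool(res.status > 0)
        message = str(res.message)
    ic = information_criteria(err, n_elements, n_free)
    return FitResult(
        params=params, err=err, n_elements=n_elements, n_params=n_free,
        aic=ic.aic, aicc=ic.aicc, bic=ic.bic, converged=converged,
        message=message, seed=seed, n_passes=n_passes, n_starts=n_starts,
        start_errs=start_errs,
    )


def replicate_and_average(params: AdaptiveModelParams,
                          stimulus_blocks: Sequence[np.ndarray],
                          p_alts=None, n_runs: int = 10, seed: int = 0,
                          n_passes: int = 1) -> pd.DataFrame:
    """Re-run a fitted model ``n_runs`` times and average the summaries.

    Returns a DataFrame indexed by summary element with the across-run mean
    and standard error of each element (NaN elements are skipped pairwise).
    """
    if n_runs < 2:
        raise ValueError(f"n_runs must be >= 2, got {n_runs}")
    by_condition = p_alts is not None and len(set(p_alts)) > 1
    runs = []
    for irun in range(n_runs):
        child = int(np.random.SeedSequence([seed, irun]).generate_state(1)[0]
                    % (2 ** 31))
        runs.append(model_summary_vector(params, stimulus_blocks, p_alts,
                                         n_passes=n_passes, seed=child))
    mat = np.vstack(runs)
    if by_condition:
        conds = sorted(set(p_alts))
        names = [f"pA{p:g}:{e}" for p in conds for e in analysis.SUMMARY_ELEMENTS]
    else:
        names = list(analysis.SUMMARY_ELEMENTS)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # all-NaN columns (elements never defined) are legitimate here
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        count = np.sum(np.isfinite(mat), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
        se = np.where(count > 1, sd / np.sqrt(np.maximum(count, 1)), np.nan)
    return pd.DataFrame({"mean": mean, "se": se, "n_runs": count},
                        index=names)
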