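"""Compiled kernels for first-passage statistics and the per-trial session loop.

Everything here is written in terms of *decaying* exponentials of the
composite quantity ``z_tilde * mu_tilde`` so that large drift-to-threshold
products (well past 20, where naive sinh/cosh expressions overflow) evaluate
without intermediate infinities.  The scaled diffusion has unit drift and
variance ``1 / mu_tilde``, so the characteristic exponent is
``beta = 2 * mu_tilde``.

The public package API wraps these kernels; they are also used directly by
the fitting objective where per-call overhead matters.
"""

from __future__ import annotations

import numpy as np
from numba import njit, vectorize

#: fraction of the threshold by which |x0| is kept strictly inside (-z, z)
#: when upstream clamping would otherwise produce equality.
EPS_FRAC = 1e-9

_SIG = "float64(float64, float64, float64)"


@njit(cache=True)
def _fp_conditional(theta, a, x):
    """Error rate and conditional mean decision times.

    Parameters are the scaled drift-to-noise rate ``theta`` (= mu_tilde),
    threshold ``a`` (= z_tilde, seconds) and initial condition ``x``
    (= x0_tilde, seconds), with ``|x| <= a``.

    Returns ``(er, dt_correct, dt_error)``.  A conditional mean is NaN when
    the conditioning event has probability zero.  The expressions are the
    closed-form solutions h+/-(x) of the backward boundary-value problems
    m h' + (s^2/2) h'' = -pi(x), h(+-a) = 0, divided by the splitting
    probabilities; they satisfy (1-er)*dt_correct + er*dt_error = <DT>.
    """
    E = np.exp(-4.0 * a * theta)            # e^{-beta * 2a}
    E1 = np.exp(-2.0 * theta * (a + x))     # e^{-beta * (a + x)}
    one = 1.0 - E
    p_correct = (1.0 - E1) / one
    if p_correct < 0.0:
        p_correct = 0.0
    elif p_correct > 1.0:
        p_correct = 1.0
    er = 1.0 - p_correct

    hp = (-x - x * E1 + a * (1.0 + E)) / one + a * (3.0 + E) * (E - E1) / one ** 2
    hm = (x * E + x * E1 - 2.0 * a * E) / one + a * (1.0 + 3.0 * E) * (E1 - E) / one ** 2

    # denominators kept nonzero so the compiled ufunc never raises FP flags
    dtc = hp / (p_correct if p_correct > 0.0 else 1.0)
    dte = hm / (er if er > 0.0 else 1.0)
    if p_correct > 0.0:
        if dtc < 0.0:
            dtc = 0.0
    else:
        dtc = np.nan
    if er > 0.0:
        if dte < 0.0:
            dte = 0.0
    else:
        dte = np.nan
    return er, dtc, dte


@vectorize([_SIG], cache=True)
def er_ufunc(theta, a, x):
    """Error probability of the scaled diffusion started at x in (-a, a)."""
    E = np.exp(-4.0 * a * theta)
    E1 = np.exp(-2.0 * theta * (a + x))
    er = (E1 - E) / (1.0 - E)
    if er < 0.0:
        er = 0.0
    elif er > 1.0:
        er = 1.0
    return er


@vectorize([_SIG], cache=True)
def dt_mean_ufunc(theta, a, x):
    """Mean decision time (seconds), unconditional on correctness."""
    E = np.exp(-4.0 * a * theta)
    Eh = np.exp(-2.0 * a * theta)
    E1 = np.exp(-2.0 * theta * (a + x))
    dt = a * np.tanh(a * theta) + 2.0 * a * (Eh - E1) / (1.0 - E) - x
    if dt < 0.0:
        dt = 0.0
    return dt


@vectorize([_SIG], cache=True)
def dt_correct_ufunc(theta, a, x):
    er, dtc, dte = _fp_conditional(theta, a, x)
    return dtc


@vectorize([_SIG], cache=True)
def dt_error_ufunc(theta, a, x):
    er, dtc, dte = _fp_conditional(theta, a, x)
    return dte


@njit(cache=True)
def mc_core(mu, sigma, z, x0, step, n_paths, max_steps, seed, bridge):
    """Euler–Maruyama first-passage kernel.

    Returns per-path arrays ``(side, n_steps)``: side = +1 absorbed at +z,
    -1 at -z, 0 unabsorbed within ``max_steps``.  With ``bridge`` a
    Brownian-bridge test catches within-step boundary touches.  Seeded and
    single-threaded, hence deterministic.
    """
    np.random.seed(seed)
    side = np.zeros(n_paths, np.int8)
    steps = np.zeros(n_paths, np.int64)
    sq_dt = np.sqrt(step)
    var_dt = sigma * sigma * step
    for ip in range(n_paths):
        x = x0
        for istep in range(1, max_steps + 1):
            xn = x + mu * step + sigma * sq_dt * np.random.normal()
            if xn >= z:
                side[ip] = 1
                steps[ip] = istep
                break
            if xn <= -z:
                side[ip] = -1
                steps[ip] = istep
                break
            if bridge:
                # bridge touch probability exp(-2 d1 d2 / var_dt) is
                # negligible (< e^-32) unless the path is near a boundary;
                # skip the exp calls in the common interior case
                du = (z - x) * (z - xn)
                dl = (x + z) * (xn + z)
                lim = 16.0 * var_dt
                if du < lim or dl < lim:
                    pu = np.exp(-2.0 * du / var_dt) if du < lim else 0.0
                    pl = np.exp(-2.0 * dl / var_dt) if dl < lim else 0.0
                    uu = np.random.random()
                    if uu < pu:
                        side[ip] = 1
                        steps[ip] = istep
                        break
                    if uu < pu + pl:
                        side[ip] = -1
                        steps[ip] = istep
                        break
            x = xn
    return side, steps


@njit(cache=True)
def session_core(stim, reset, u,
                 mu_tilde, t_nd, k, x_offset, delta, z_down, z_up, z_max):
    """Run the adaptive model through one pass of a stimulus sequence.

    ``stim`` is an int array of {1, 2}; ``reset[i]`` marks positions where the
    model state re-initializes (memory 1/2, threshold z_max); ``u`` holds one
    pre-drawn uniform variate per trial deciding correctness (u < ER -> error).

    Per trial: the starting point is primed from the repetition memory and the
    upcoming transition sign, the error probability comes from the closed-form
    ER at the current threshold, correctness is a biased coin flip, and the RT
    is the non-decision time plus the correct- or error-conditional mean
    decision time.  Memory is held at 1/2 through the first two trials of a
    run; the threshold steps down after correct trials and up after errors,
    clamped to [k/2 + x_offset, z_max].

    Returns (correct, rt, x0, z, memory, transition) arrays; transition codes
    are 1 = repetition, 0 = alternation, -1 = undefined (first trial of a run).
    """
    n = stim.shape[0]
    correct = np.empty(n, np.uint8)
    rt = np.empty(n)
    x0_out = np.empty(n)
    z_out = np.empty(n)
    mem_out = np.empty(n)
    trans = np.empty(n, np.int8)

    z_lo = 0.5 * k + x_offset
    mem = 0.5
    z = z_max
    n_in_run = 0
    for i in range(n):
        if reset[i]:
            mem = 0.5
            z = z_max
            n_in_run = 0
        n_in_run += 1

        if n_in_run == 1:
            t = np.int8(-1)
            x0 = 0.0
        else:
            t = np.int8(1) if stim[i] == stim[i - 1] else np.int8(0)
            s = 1.0 if t == 1 else -1.0
            x0 = s * (k * (mem - 0.5) + x_offset)

        lim = z * (1.0 - EPS_FRAC)
        if x0 > lim:
            x0 = lim
        elif x0 < -lim:
            x0 = -lim

        er, dtc, dte = _fp_conditional(mu_tilde, z, x0)
        is_err = u[i] < er
        if is_err:
            correct[i] = 0
            rt[i] = t_nd + dte
        else:
            correct[i] = 1
            rt[i] = t_nd + dtc

        x0_out[i] = x0
        z_out[i] = z
        mem_out[i] = mem
        trans[i] = t

        if n_in_run >= 3:
            mem = delta * mem + (1.0 - delta) * (1.0 if t == 1 else 0.0)
        z = z + (z_up if is_err else -z_down)
        if z > z_max:
            z = z_max
        elif z < z_lo:
            z = z_lo
    return correct, rt, x0_out, z_out, mem_out, trans
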