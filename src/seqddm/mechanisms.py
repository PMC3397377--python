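"""Trial-to-trial dynamics of the adapted drift-diffusion model.

Two mechanisms ride on top of the pure DDM of :mod:`seqddm.ddm`:

* a *priming* mechanism — an exponentially filtered memory of repetitions
  M(n) in [0, 1] sets the next trial's starting point
  ``x0 = s * (k * (M - 1/2) + x_offset)`` with sign ``s = +1`` when the
  upcoming trial repeats the previous stimulus and ``-1`` when it alternates;
* an *error-correcting* mechanism — the (symmetric) threshold steps down by
  ``z_down`` after a correct response and up by ``z_up`` after an error,
  clamped to ``[k/2 + x_offset, z_max]``.

Together with the scaled drift ``mu_tilde`` and the non-decision time
``t_nd`` these form the eight-parameter adaptive model.  Per trial the error
probability comes from the closed-form ER at the current threshold and
starting point, correctness is decided by a biased coin flip, and the RT is
the non-decision time plus the correct- or error-conditional mean decision
time (no sampling from the full RT distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _fast

REPETITION = "R"
ALTERNATION = "A"

_TRANSITION_ALIASES = {
    "R": REPETITION, "repetition": REPETITION,
    "A": ALTERNATION, "alternation": ALTERNATION,
}


def _norm_transition(transition):
    if transition is None:
        return None
    try:
        return _TRANSITION_ALIASES[transition]
    except KeyError:
        raise ValueError(
            f"transition must be 'R', 'A' or None, got {transition!r}"
        ) from None


@dataclass(frozen=True)
class AdaptiveModelParams:
    """The eight parameters of the adaptive model.

    mu_tilde : scaled drift (signal-to-noise rate), 1/seconds
    t_nd     : non-decision time, seconds
    k        : priming scale (seconds per unit memory deviation)
    x_offset : fixed starting-point bias magnitude, seconds
    delta    : memory decay per trial, in (0, 1)
    z_down   : post-correct threshold decrement, seconds
    z_up     : post-error threshold increment, seconds
    z_max    : threshold ceiling (and initial threshold), seconds

    The admissible threshold range ``[k/2 + x_offset, z_max]`` must be
    non-empty.
    """

    mu_tilde: float
    t_nd: float
    k: float
    x_offset: float
    delta: float
    z_down: float
    z_up: float
    z_max: float

    def __post_init__(self):
        for name in ("mu_tilde", "t_nd", "k", "x_offset", "z_down", "z_up", "z_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.mu_tilde <= 0:
            raise ValueError(f"mu_tilde must be > 0, got {self.mu_tilde}")
        if self.z_max <= 0:
            raise ValueError(f"z_max must be > 0, got {self.z_max}")
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.z_max < self.z_floor:
            raise ValueError(
                f"z_max ({self.z_max}) must be >= k/2 + x_offset ({self.z_floor}): "
                "the admissible threshold range is empty"
            )

    @property
    def z_floor(self) -> float:
        """Lower threshold bound, k/2 + x_offset (seconds)."""
        return 0.5 * self.k + self.x_offset

    def astuple(self):
        return (self.mu_tilde, self.t_nd, self.k, self.x_offset, self.delta,
                self.z_down, self.z_up, self.z_max)


#: Fitted parameters for the unbiased letter-discrimination session
#: (13 blocks x 120 trials, P_A = 50%).
EXPERIMENT1_FIT = AdaptiveModelParams(
    mu_tilde=38.1747, t_nd=0.2626, k=0.0943, x_offset=0.0051,
    delta=0.6860, z_down=0.0058, z_up=0.0348, z_max=0.2857,
)

#: Fitted parameters for the transition-biased dot-motion session
#: (9 blocks x 200 trials, P_A in {10%, 50%, 90%}).
EXPERIMENT2_FIT = AdaptiveModelParams(
    mu_tilde=19.3312, t_nd=0.3359, k=0.1181, x_offset=0.0034,
    delta=0.6882, z_down=0.0034, z_up=0.1635, z_max=0.2062,
)


@dataclass(frozen=True)
class ModelState:
    """Evolving per-run model state: repetition memory, current threshold and
    the number of completed trials in the run."""

    memory: float
    z_current: float
    trial_index: int = 0

    def __post_init__(self):
        if not 0.0 <= self.memory <= 1.0:
            raise ValueError(f"memory must be in [0, 1], got {self.memory}")
        if self.z_current <= 0:
            raise ValueError(f"z_current must be > 0, got {self.z_current}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


def initial_state(params: AdaptiveModelParams) -> ModelState:
    """Unbiased starting state: memory 1/2, threshold at the ceiling."""
    return ModelState(memory=0.5, z_current=params.z_max, trial_index=0)


def update_memory(memory: float, transition, delta: float) -> float:
    """Exponential-filter update of the repetition memory.

    Repetition: ``delta * memory + (1 - delta)``; alternation:
    ``delta * memory``.  Maps [0, 1] into [0, 1]; ``delta`` close to 1 means
    long memory of the transition history.
    """
    if not 0.0 <= memory <= 1.0:
        raise ValueError(f"memory must be in [0, 1], got {memory}")
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    t = _norm_transition(transition)
    if t is None:
        raise ValueError("transition must be 'R' or 'A' for a memory update")
    if t == REPETITION:
        return delta * memory + (1.0 - delta)
    return delta * memory


def initial_condition(memory: float, transition, k: float,
                      x_offset: float) -> float:
    """Primed starting point for the upcoming trial (seconds).

    ``s * (k * (memory - 1/2) + x_offset)`` with s = +1 for a repetition and
    -1 for an alternation; bounded by ``k/2 + x_offset`` in magnitude.
    """
    if not 0.0 <= memory <= 1.0:
        raise ValueError(f"memory must be in [0, 1], got {memory}")
    t = _norm_transition(transition)
    if t is None:
        return 0.0
    s = 1.0 if t == REPETITION else -1.0
    return s * (k * (memory - 0.5) + x_offset)


def update_threshold(z_current: float, was_correct: bool,
                     params: AdaptiveModelParams) -> float:
    """Post-trial threshold step, clamped to [k/2 + x_offset, z_max]."""
    z = z_current + (-params.z_down if was_correct else params.z_up)
    return min(max(z, params.z_floor), params.z_max)


class TrialResult(NamedTuple):
    stimulus: int
    transition: str | None
    x0: float
    z: float
    er: float
    correct: bool
    response: int
    rt: float
    memory: float


def simulate_trial(state: ModelState, transition, stimulus: int,
                   params: AdaptiveModelParams,
                   rng: np.random.Generator) -> tuple[TrialResult, ModelState]:
    """Simulate one trial and return the outcome plus the successor state.

    Draws exactly one uniform variate from ``rng`` (u < ER decides an error),
    so a fixed generator state yields identical results.  ``transition`` is
    None on the first trial of a run (unprimed start, x0 = 0).
    """
    if stimulus not in (1, 2):
        raise ValueError(f"stimulus must be 1 or 2, got {stimulus}")
    t = _norm_transition(transition)
    n = state.trial_index + 1

    x0 = initial_condition(state.memory, t, params.k, params.x_offset)
    z = state.z_current
    lim = z * (1.0 - _fast.EPS_FRAC)
    x0 = min(max(x0, -lim), lim)

    er, dtc, dte = _fast._fp_conditional(params.mu_tilde, z, x0)
    u = rng.random()
    is_error = bool(u < er)
    rt = params.t_nd + (dte if is_error else dtc)
    correct = not is_error
    response = stimulus if correct else 3 - stimulus

    # memory is held at 1/2 through the first two trials of a run
    if n >= 3 and t is not None:
        new_memory = update_memory(state.memory, t, params.delta)
    else:
        new_memory = 0.5 if n <= 2 else state.memory
    new_z = update_threshold(z, correct, params)
    new_state = replace(state, memory=new_memory, z_current=new_z,
                        trial_index=n)
    result = TrialResult(stimulus=stimulus, transition=t, x0=x0, z=z, er=er,
                         correct=correct, response=response, rt=rt,
                         memory=state.memory)
    return result, new_state


_TRANS_STR = {1: REPETITION, 0: ALTERNATION, -1: None}


def prepare_session(stimulus_blocks: Sequence[np.ndarray],
                    n_passes: int = 1,
                    seed: int | None = None,
                    p_alt=None,
                    reset_per_block: bool = True) -> dict:
    """Pre-draw the stimuli layout and per-trial uniforms for a session run.

    The returned dict can be replayed against any parameter set with
    :func:`run_prepared_session`, which is what gives the fitting objective
    common random numbers across evaluations without re-deriving the RNG
    streams each time.
    """
    if n_passes < 1:
        raise ValueError(f"n_passes must be >= 1, got {n_passes}")
    blocks = [np.asarray(b, dtype=np.int64) for b in stimulus_blocks]
    if len(blocks) == 0 or any(b.size == 0 for b in blocks):
        raise ValueError("stimulus_blocks must be non-empty arrays")
    for b in blocks:
        if not np.isin(b, (1, 2)).all():
            raise ValueError("stimuli must take values in {1, 2}")

    if p_alt is None:
        p_alts = [np.nan] * len(blocks)
    elif np.isscalar(p_alt):
        p_alts = [float(p_alt)] * len(blocks)
    else:
        if len(p_alt) != len(blocks):
            raise ValueError("p_alt must be scalar or one value per block")
        p_alts = [float(p) for p in p_alt]

    sizes = [b.size for b in blocks]
    stim1 = np.concatenate(blocks)
    n1 = stim1.size
    reset1 = np.zeros(n1, dtype=np.bool_)
    starts = np.cumsum([0] + sizes[:-1])
    if reset_per_block:
        reset1[starts] = True
    else:
        reset1[0] = True
    block_id1 = np.repeat(np.arange(1, len(blocks) + 1), sizes)
    trial1 = np.concatenate([np.arange(1, s + 1) for s in sizes])
    p_alt1 = np.repeat(np.asarray(p_alts, dtype=float), sizes)

    root = seed if seed is not None else np.random.SeedSequence().entropy
    u = np.concatenate([
        np.random.default_rng(
            np.random.SeedSequence([root, ipass, ib])).random(s)
        for ipass in range(1, n_passes + 1)
        for ib, s in enumerate(sizes, start=1)
    ])
    n_blocks = len(blocks)
    pass_no = np.repeat(np.arange(1, n_passes + 1), n1)
    if reset_per_block:
        run_id = pass_no * (n_blocks + 1) + np.tile(block_id1, n_passes)
    else:
        run_id = pass_no.copy()
    return {
        "stim": np.tile(stim1, n_passes),
        "reset": np.tile(reset1, n_passes),
        "u": u,
        "pass": pass_no,
        "block": np.tile(block_id1, n_passes),
        "trial": np.tile(trial1, n_passes),
        "p_alt": np.tile(p_alt1, n_passes),
        "run_id": run_id,
        "n_passes": n_passes,
    }


def run_prepared_session(prep: dict, params: AdaptiveModelParams) -> dict:
    """Replay a prepared session against one parameter set (flat arrays)."""
    correct, rt, x0, z, mem, trans = _fast.session_core(
        prep["stim"], prep["reset"], prep["u"], *params.astuple())
    correct = correct.astype(bool)
    return {
        "pass": prep["pass"],
        "block": prep["block"],
        "trial": prep["trial"],
        "p_alt": prep["p_alt"],
        "stimulus": prep["stim"],
        "transition": trans,
        "correct": correct,
        "rt": rt,
        "x0": x0,
        "z": z,
        "memory": mem,
        "response": np.where(correct, prep["stim"], 3 - prep["stim"]),
        "run_id": prep["run_id"],
    }


def simulate_session(stimulus_blocks: Sequence[np.ndarray],
                     params: AdaptiveModelParams,
                     n_passes: int = 1,
                     seed: int | None = None,
                     p_alt=None,
                     subject: str | None = None,
                     reset_per_block: bool = True,
                     as_frame: bool = True):
    """Run the model ``n_passes`` times through a session's stimulus blocks.

    ``stimulus_blocks`` is a sequence of 1-D integer arrays over {1, 2}, one
    per block; ``p_alt`` optionally gives the block transition probability
    (scalar or one value per block) carried through to the output.  Model
    state re-initializes at every block boundary by default (memory 1/2,
    threshold at the ceiling); with ``reset_per_block=False`` state carries
    across blocks and only the session start is unprimed.

    Randomness: each (pass, block) gets an independent child stream derived
    from ``seed``, so increasing ``n_passes`` extends the table without
    reshuffling earlier passes.

    Returns a trial table (one row per simulated trial, ``pass`` column
    recording the pass) as a DataFrame, or a dict of flat numpy arrays when
    ``as_frame=False``.
    """
    prep = prepare_session(stimulus_blocks, n_passes=n_passes, seed=seed,
                           p_alt=p_alt, reset_per_block=reset_per_block)
    flat = run_prepared_session(prep, params)
    if not as_frame:
        return flat

    df = pd.DataFrame({
        "block": flat["block"],
        "trial": flat["trial"],
        "p_alt": flat["p_alt"],
        "pass": flat["pass"],
        "stimulus": flat["stimulus"],
        "transition": [_TRANS_STR[t] for t in flat["transition"]],
        "response": flat["response"],
        "correct": flat["correct"],
        "rt": flat["rt"],
        "x0": flat["x0"],
        "z": flat["z"],
        "memory": flat["memory"],
    })
    if subject is not None:
        df.insert(0, "subject", subject)
    return df
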