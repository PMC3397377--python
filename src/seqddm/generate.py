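"""Synthetic stimulus sequences, experiment schedules and model subjects.

Stimulus order is a transition-oriented first-order Markov process: given the
current stimulus, the next one alternates with probability ``p_alt`` and
repeats with probability ``1 - p_alt``.  Two canned session designs are
provided:

* ``exp1`` — 13 blocks of 120 trials, all with p_alt = 0.5 (an unbiased
  letter-discrimination control session);
* ``exp2`` — 9 blocks of 200 trials, p_alt in {0.1, 0.5, 0.9} with exactly 3
  blocks each, in a seeded balanced-random order (a per-subject stand-in for
  the Latin-square counterbalancing used with human participants, which
  matters for fatigue, not for the model).

A synthetic subject is a model run (single pass) of the adaptive DDM over
such a schedule, with the generating parameters kept alongside for parameter
recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanisms import AdaptiveModelParams, simulate_session


@dataclass(frozen=True)
class StimulusBlockConfig:
    """One block of Markov stimuli: alternation probability, length, seed."""

    p_alt: float
    n_trials: int
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_alt <= 1.0:
            raise ValueError(f"p_alt must be in [0, 1], got {self.p_alt}")
        if self.n_trials < 3:
            raise ValueError(
                f"n_trials must be >= 3 (three-trial sequence labels), "
                f"got {self.n_trials}"
            )


@dataclass(frozen=True)
class ExperimentSchedule:
    """An ordered list of stimulus blocks plus a design tag."""

    blocks: tuple[StimulusBlockConfig, ...]
    design: str = "custom"

    def __post_init__(self):
        if len(self.blocks) == 0:
            raise ValueError("schedule must contain at least one block")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def p_alts(self) -> tuple[float, ...]:
        return tuple(b.p_alt for b in self.blocks)


def generate_markov_stimuli(config: StimulusBlockConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one block's stimulus sequence over {1, 2}.

    The first stimulus is equiprobable; each subsequent stimulus alternates
    with probability ``config.p_alt``.  Deterministic given ``config.seed``
    (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    stim = np.empty(n, dtype=np.int64)
    stim[0] = rng.integers(1, 3)
    flips = rng.random(n - 1) < config.p_alt
    for i in range(1, n):
        stim[i] = (3 - stim[i - 1]) if flips[i - 1] else stim[i - 1]
    return stim


_DESIGNS = {
    "exp1": dict(n_blocks=13, n_trials=120, p_alts=(0.5,) * 13),
    "exp2": dict(n_blocks=9, n_trials=200,
                 p_alts=(0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9)),
}


def generate_experiment_schedule(design: str,
                                 seed: int | None = None) -> ExperimentSchedule:
    """Build the block schedule for a canned design tag.

    For ``exp2`` the three blocks of each alternation probability are placed
    in a seeded random order (balanced: exactly 3 blocks per p_alt); for
    ``exp1`` all blocks are identical so no ordering applies.  Each block
    receives its own child seed derived from ``seed``.
    """
    if design not in _DESIGNS:
        raise ValueError(
            f"unknown design {design!r}; expected one of {sorted(_DESIGNS)}"
        )
    layout = _DESIGNS[design]
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 777]))
    p_alts = np.asarray(layout["p_alts"], dtype=float)
    if design == "exp2":
        p_alts = p_alts[rng.permutation(len(p_alts))]
    block_seeds = [
        int(np.random.SeedSequence(
            [0 if seed is None else seed, ib]).generate_state(1)[0])
        for ib in range(1, layout["n_blocks"] + 1)
    ]
    blocks = tuple(
        StimulusBlockConfig(p_alt=float(p), n_trials=layout["n_trials"], seed=s)
        for p, s in zip(p_alts, block_seeds)
    )
    return ExperimentSchedule(blocks=blocks, design=design)


def generate_schedule_stimuli(schedule: ExperimentSchedule) -> list[np.ndarray]:
    """Draw the stimulus arrays for every block of a schedule."""
    return [generate_markov_stimuli(b) for b in schedule.blocks]


def generate_synthetic_subject(true_params: AdaptiveModelParams,
                               schedule: ExperimentSchedule,
                               seed: int | None = None,
                               subject: str = "synth",
                               ) -> tuple[pd.DataFrame, dict]:
    """Generate one ground-truth model subject over a schedule.

    Stimuli are drawn per block from the schedule's Markov configs and the
    responses come from a single pass of the adaptive model.  Returns the
    trial table and a ground-truth record (parameters, design, seeds) for
    parameter-recovery studies.
    """
    stimuli = generate_schedule_stimuli(schedule)
    table = simulate_session(
        stimuli, true_params, n_passes=1, seed=seed,
        p_alt=schedule.p_alts, subject=subject,
    )
    truth = {
        "subject": subject,
        "design": schedule.design,
        "seed": seed,
        "block_seeds": [b.seed for b in schedule.blocks],
        "p_alts": list(schedule.p_alts),
        "n_trials_per_block": [b.n_trials for b in schedule.blocks],
        "params": {
            "mu_tilde": true_params.mu_tilde,
            "t_nd": true_params.t_nd,
            "k": true_params.k,
            "x_offset": true_params.x_offset,
            "delta": true_params.delta,
            "z_down": true_params.z_down,
            "z_up": true_params.z_up,
            "z_max": true_params.z_max,
        },
    }
    return table, truth


def write_ground_truth(truth: dict, path) -> None:
    """Write the ground-truth sidecar record as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
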