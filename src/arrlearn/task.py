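"""Interleaved two-task probabilistic learning paradigm: design generation and validation.

Participants (or simulated agents) perform two probabilistic selection tasks in
interleaved trials.  The *inducer* task controls the average reward rate by
rewarding the better option with probability 7/12 (low), 9/12 (medium) or 11/12
(high); the *reference* task always uses 9/12.  A session is one training block
plus 15 experiment-proper blocks of 24 trials (12 per task), with a fresh
stimulus pair per task per block (32 pairs in total).

Outcome schedules are fixed-ratio: within a task-block, exactly ``k`` of the
better option's 12 pre-drawn outcomes are positive (and exactly ``k`` of the
worse option's are negative), so realized reward probabilities equal the
nominal ratios regardless of the agent's choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

CONDITIONS: Tuple[str, ...] = ("low", "medium", "high")
TASKS: Tuple[str, ...] = ("inducer", "reference")
SIDES: Tuple[str, ...] = ("left", "right")

#: positive outcomes per 12 trials for the better option, by condition
N_POSITIVE_PER_12: Dict[str, int] = {"low": 7, "medium": 9, "high": 11}

N_BLOCKS = 15
TRIALS_PER_TASK = 12
TRIALS_PER_BLOCK = 2 * TRIALS_PER_TASK
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK  # experiment proper
N_PAIRS = 2 * (N_BLOCKS + 1)  # includes the training block
MAX_RUN = 3  # longest allowed run of one task in the interleaving
TIMEOUT_PENALTY = -2.0

#: condition assigned to the training block (both tasks); the neutral design point
TRAINING_CONDITION = "medium"


@dataclass(frozen=True)
class Condition:
    """One inducer reward-probability level."""

    label: str

    def __post_init__(self):
        if self.label not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.label!r}")

    @property
    def n_positive_per_12(self) -> int:
        return N_POSITIVE_PER_12[self.label]

    @property
    def p_reward(self) -> float:
        """Reward probability of the better option (= punishment probability of the worse)."""
        return self.n_positive_per_12 / 12.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Feedback magnitudes of one experiment.

    ``feedback_magnitudes`` maps ``(task, condition, valence)`` to points, with
    valence in ``{"positive", "negative"}``.  The reference task's magnitudes
    are constant across conditions.
    """

    experiment_id: int
    feedback_magnitudes: Dict[Tuple[str, str, str], float]
    timeout_penalty: float = TIMEOUT_PENALTY

    def magnitude(self, task: str, condition: str, valence: str) -> float:
        return self.feedback_magnitudes[(task, condition, valence)]


def experiment_config(experiment_id: int) -> ExperimentConfig:
    """Build the feedback-magnitude table for experiment 1, 2 or 3.

    Experiment 1: +1/-1 everywhere.  Experiment 2: reference +1/-1; inducer
    +3/-3 (low), +1/-1 (medium), +0.6/-0.6 (high) -- chosen so an always-correct
    agent earns 0.5 points/trial in every inducer condition.  Experiment 3:
    positive +1, negative 0 everywhere.
    """
    mags: Dict[Tuple[str, str, str], float] = {}
    if experiment_id == 1:
        for task in TASKS:
            for cond in CONDITIONS:
                mags[(task, cond, "positive")] = 1.0
                mags[(task, cond, "negative")] = -1.0
    elif experiment_id == 2:
        inducer_mag = {"low": 3.0, "medium": 1.0, "high": 0.6}
        for cond in CONDITIONS:
            mags[("inducer", cond, "positive")] = inducer_mag[cond]
            mags[("inducer", cond, "negative")] = -inducer_mag[cond]
            mags[("reference", cond, "positive")] = 1.0
            mags[("reference", cond, "negative")] = -1.0
    elif experiment_id == 3:
        for task in TASKS:
            for cond in CONDITIONS:
                mags[(task, cond, "positive")] = 1.0
                mags[(task, cond, "negative")] = 0.0
    else:
        raise ValueError(f"experiment_id must be 1, 2 or 3, got {experiment_id!r}")
    return ExperimentConfig(experiment_id=experiment_id, feedback_magnitudes=mags)


@dataclass
class BlockSpec:
    """One block: 24 interleaved trials of two tasks with fixed-ratio schedules.

    ``outcome_schedule[task]`` is a pair of length-12 arrays of +1/-1 valences:
    the outcome delivered if the better (resp. worse) option is chosen on that
    task's trial 1..12.  ``better_side`` gives, per block trial, the screen side
    of the better option (used for the button-run exclusion rule).
    """

    block_index: int  # 0 = training, 1..15 = experiment proper
    condition: str  # applies to the inducer task; reference is always 9/12
    task_order: List[str]
    pair_ids: Dict[str, str]
    outcome_schedule: Dict[str, Tuple[np.ndarray, np.ndarray]]
    better_side: List[str] = field(default_factory=list)

    def task_reward_ratio(self, task: str) -> int:
        """Positive outcomes per 12 for the better option of ``task`` in this block."""
        if task == "reference":
            return N_POSITIVE_PER_12["medium"]
        return N_POSITIVE_PER_12[self.condition]


@dataclass
class SessionSpec:
    """A participant's full design: one training block plus 15 blocks."""

    experiment_config: ExperimentConfig
    training_block: BlockSpec
    blocks: List[BlockSpec]
    rng_seed: int | None = None

    @property
    def all_blocks(self) -> List[BlockSpec]:
        return [self.training_block] + list(self.blocks)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_condition_sequence(rng) -> List[str]:
    """Draw a 15-block condition sequence as 5 independent permutations of the
    three conditions, so every consecutive triplet contains each condition once
    and each condition occurs exactly 5 times."""
    rng = _as_rng(rng)
    seq: List[str] = []
    for _ in range(5):
        seq.extend(rng.permutation(CONDITIONS).tolist())
    return seq


def make_trial_interleaving(rng) -> List[str]:
    """Shuffle 12 inducer + 12 reference labels, rejecting orders where either
    task repeats more than three times in a row."""
    rng = _as_rng(rng)
    labels = np.array(["inducer"] * TRIALS_PER_TASK + ["reference"] * TRIALS_PER_TASK)
    while True:
        order = rng.permutation(labels)
        if _max_run_length(order) <= MAX_RUN:
            return order.tolist()


def _max_run_length(seq) -> int:
    longest = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


def make_outcome_schedule(condition: str, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed-ratio valence schedules for one task-block.

    Returns ``(better, worse)``: length-12 arrays of +1/-1.  The better option
    has exactly ``k`` positive entries and the worse option exactly ``k``
    negative entries (``k`` = 7, 9 or 11), independently shuffled.
    """
    rng = _as_rng(rng)
    k = N_POSITIVE_PER_12[condition]
    better = np.array([1] * k + [-1] * (TRIALS_PER_TASK - k))
    worse = np.array([-1] * k + [1] * (TRIALS_PER_TASK - k))
    return rng.permutation(better), rng.permutation(worse)


def _make_block(block_index: int, condition: str, pair_ids: Dict[str, str],
                rng: np.random.Generator) -> BlockSpec:
    schedule = {
        "inducer": make_outcome_schedule(condition, rng),
        "reference": make_outcome_schedule("medium", rng),
    }
    return BlockSpec(
        block_index=block_index,
        condition=condition,
        task_order=make_trial_interleaving(rng),
        pair_ids=dict(pair_ids),
        outcome_schedule=schedule,
        better_side=[SIDES[i] for i in rng.integers(0, 2, TRIALS_PER_BLOCK)],
    )


def generate_session(config: ExperimentConfig, rng) -> SessionSpec:
    """Generate a complete session design satisfying all paradigm constraints."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    pair_counter = iter(range(N_PAIRS))

    def next_pairs() -> Dict[str, str]:
        return {task: f"P{next(pair_counter):02d}" for task in TASKS}

    training = _make_block(0, TRAINING_CONDITION, next_pairs(), rng)
    conditions = make_condition_sequence(rng)
    blocks = [_make_block(i + 1, cond, next_pairs(), rng)
              for i, cond in enumerate(conditions)]
    return SessionSpec(experiment_config=config, training_block=training,
                       blocks=blocks, rng_seed=seed)


def expected_points_per_trial(config: ExperimentConfig, task: str, condition: str,
                              p_correct: float = 1.0) -> float:
    """Expected feedback points per trial of ``task`` under ``condition``.

    ``p_correct`` is the probability of choosing the better option; the default
    1.0 gives the always-correct expectation used to verify that experiment 2's
    magnitudes equalize average reward across inducer conditions.
    """
    cond = Condition("medium") if task == "reference" else Condition(condition)
    pos = config.magnitude(task, condition, "positive")
    neg = config.magnitude(task, condition, "negative")
    p = cond.p_reward
    e_better = p * pos + (1.0 - p) * neg
    e_worse = (1.0 - p) * pos + p * neg
    return p_correct * e_better + (1.0 - p_correct) * e_worse


def validate_session(session) -> List[str]:
    """Check every paradigm invariant; return a list of violation messages.

    An empty list means the session is valid.  Structurally malformed input
    raises ``ValueError`` naming the missing field.
    """
    for attr in ("experiment_config", "training_block", "blocks"):
        if not hasattr(session, attr):
            raise ValueError(f"malformed session: missing field {attr!r}")

    problems: List[str] = []
    blocks = list(session.blocks)
    if len(blocks) != N_BLOCKS:
        problems.append(f"block-count: expected {N_BLOCKS} blocks, found {len(blocks)}")

    conds = [b.condition for b in blocks]
    for label in CONDITIONS:
        n = conds.count(label)
        if n != 5:
            problems.append(f"condition-count: condition {label!r} occurs {n} times, expected 5")
    for i in range(0, len(conds) - 2, 3):
        triplet = conds[i:i + 3]
        if sorted(triplet) != sorted(CONDITIONS):
            problems.append(
                f"condition-sequence: blocks {i + 1}-{i + 3} triplet {triplet} "
                "is not a permutation of the three conditions")

    pair_ids = set()
    for block in [session.training_block] + blocks:
        where = f"block {block.block_index}"
        order = list(block.task_order)
        if len(order) != TRIALS_PER_BLOCK:
            problems.append(f"interleaving: {where} has {len(order)} trials, expected {TRIALS_PER_BLOCK}")
        for task in TASKS:
            if order.count(task) != TRIALS_PER_TASK:
                problems.append(
                    f"interleaving: {where} has {order.count(task)} {task} trials, expected {TRIALS_PER_TASK}")
        if _max_run_length(order) > MAX_RUN:
            problems.append(
                f"interleaving: {where} repeats one task more than {MAX_RUN} trials in a row")
        for task in TASKS:
            pair_ids.add(block.pair_ids[task])
            better, worse = block.outcome_schedule[task]
            k = block.task_reward_ratio(task)
            n_pos_better = int(np.sum(np.asarray(better) > 0))
            n_neg_worse = int(np.sum(np.asarray(worse) < 0))
            if len(better) != TRIALS_PER_TASK or len(worse) != TRIALS_PER_TASK:
                problems.append(f"schedule: {where} {task} schedule is not length {TRIALS_PER_TASK}")
                continue
            if n_pos_better != k:
                problems.append(
                    f"schedule: {where} {task} better option has {n_pos_better} positives, expected {k}")
            if n_neg_worse != k:
                problems.append(
                    f"schedule: {where} {task} worse option has {n_neg_worse} negatives, expected {k}")
    if len(pair_ids) != N_PAIRS:
        problems.append(f"pairs: found {len(pair_ids)} distinct pair ids, expected {N_PAIRS}")
    return problems
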