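"""The nine-model Q-learning family with a shared average-reward accumulator.

All models learn option values by delta-rule updates,

    Q_i <- Q_i + alpha * delta,      delta = R - Q_i,

and choose via a softmax with decision weight beta.  The three *null* models
(``null-a``, ``null-aPE``, ``null-aR``) treat the two interleaved tasks as
independent.  The six average-reward-rate (ARR) models add a single scalar
accumulator ``mu`` shared across both tasks, updated on every non-missed trial
either from prediction errors (``*-PE``: mu <- mu + alpha_mu*(delta - mu)) or
from rewards (``*-R``: mu <- mu + alpha_mu*(R - mu)), and let mu modulate one
of three targets:

- ``FB-*``: the prediction error itself, delta = R - Q + mu
- ``a-*``:  the learning rate, alpha(t) = clip(alpha_0*(1 + mu), 0, 1)
- ``b-*``:  the decision weight, beta(t) = max(0, beta_0*(1 + mu))

mu is the hypothesized carrier of motivational transfer between the tasks: a
low reward rate in the inducer task depresses mu and thereby learning in the
interleaved reference task.

Conventions (fixed here, used consistently by likelihood and simulation):
Q and mu start at 0; mu resets at block boundaries; within a trial, delta is
computed with the pre-update mu, the chosen option's Q updates, then mu
updates (for ``FB-PE`` the mu update consumes the same mu-augmented delta used
for learning); missed trials contribute no likelihood and no state change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .task import SessionSpec, TRIALS_PER_TASK

MAX_PARAMS = 6

#: parameter kinds and their native bounds / unconstrained transforms
UNIT = "unit"          # [0, 1], sigmoid transform (learning rates, discounts)
POSITIVE = "positive"  # [0, inf), exponential transform (decision/outcome weights)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family."""

    name: str
    parameter_names: Tuple[str, ...]
    parameter_kinds: Tuple[str, ...]
    accumulator_kind: str   # none | prediction_error | reward
    modulation_target: str  # none | delta | learning_rate | decision_weight
    model_id: int

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


def _spec(name, names, kinds, acc, target, mid):
    return ModelSpec(name, tuple(names), tuple(kinds), acc, target, mid)


MODEL_NAMES: Tuple[str, ...] = (
    "null-a", "null-aPE", "null-aR",
    "FB-PE", "a-PE", "b-PE",
    "FB-R", "a-R", "b-R",
)

MODELS: Dict[str, ModelSpec] = {
    "null-a": _spec("null-a", ("alpha", "beta"), (UNIT, POSITIVE),
                    "none", "none", _kernels.NULL_A),
    "null-aPE": _spec("null-aPE", ("alpha_pos", "alpha_neg", "beta"),
                      (UNIT, UNIT, POSITIVE), "none", "none", _kernels.NULL_APE),
    "null-aR": _spec("null-aR",
                     ("alpha", "lambda_pos", "lambda_neg", "w_pos", "w_neg", "beta"),
                     (UNIT, UNIT, UNIT, POSITIVE, POSITIVE, POSITIVE),
                     "none", "none", _kernels.NULL_AR),
    "FB-PE": _spec("FB-PE", ("alpha", "alpha_mu", "beta"), (UNIT, UNIT, POSITIVE),
                   "prediction_error", "delta", _kernels.FB_PE),
    "a-PE": _spec("a-PE", ("alpha0", "alpha_mu", "beta"), (UNIT, UNIT, POSITIVE),
                  "prediction_error", "learning_rate", _kernels.A_PE),
    "b-PE": _spec("b-PE", ("alpha", "alpha_mu", "beta0"), (UNIT, UNIT, POSITIVE),
                  "prediction_error", "decision_weight", _kernels.B_PE),
    "FB-R": _spec("FB-R", ("alpha", "alpha_mu", "beta"), (UNIT, UNIT, POSITIVE),
                  "reward", "delta", _kernels.FB_R),
    "a-R": _spec("a-R", ("alpha0", "alpha_mu", "beta"), (UNIT, UNIT, POSITIVE),
                 "reward", "learning_rate", _kernels.A_R),
    "b-R": _spec("b-R", ("alpha", "alpha_mu", "beta0"), (UNIT, UNIT, POSITIVE),
                 "reward", "decision_weight", _kernels.B_R),
}

#: accepted aliases, including the unicode names used in the field's figures
MODEL_ALIASES: Dict[str, str] = {
    "ØØ-α": "null-a", "ØØ-αPE+-": "null-aPE", "ØØ-αR+-": "null-aR",
    "ØØ-αPE": "null-aPE", "ØØ-αR": "null-aR",
    "null-alpha": "null-a",
}


def get_model(name: str) -> ModelSpec:
    """Look up a model by canonical name or alias (case-insensitive)."""
    if name in MODELS:
        return MODELS[name]
    if name in MODEL_ALIASES:
        return MODELS[MODEL_ALIASES[name]]
    lower = {k.lower(): v for k, v in MODELS.items()}
    if name.lower() in lower:
        return lower[name.lower()]
    raise KeyError(f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}")


@dataclass
class ParameterVector:
    """Named native-space parameters of one model."""

    model: ModelSpec
    values: Dict[str, float]

    def __post_init__(self):
        missing = set(self.model.parameter_names) - set(self.values)
        extra = set(self.values) - set(self.model.parameter_names)
        if missing or extra:
            raise ValueError(
                f"parameters for {self.model.name} must be exactly "
                f"{self.model.parameter_names}; missing={sorted(missing)} extra={sorted(extra)}")

    def as_array(self) -> np.ndarray:
        return np.array([float(self.values[n]) for n in self.model.parameter_names])

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def make_parameters(model: ModelSpec | str, **values: float) -> ParameterVector:
    if isinstance(model, str):
        model = get_model(model)
    return ParameterVector(model, {k: float(v) for k, v in values.items()})


def validate_parameters(model: ModelSpec, native: np.ndarray) -> None:
    """Raise if any native value is outside its parameter-kind bounds."""
    for name, kind, v in zip(model.parameter_names, model.parameter_kinds, native):
        if kind == UNIT and not (0.0 <= v <= 1.0):
            raise ValueError(f"{model.name}: {name}={v} outside [0, 1]")
        if kind == POSITIVE and not (v >= 0.0):
            raise ValueError(f"{model.name}: {name}={v} must be >= 0")


def transform_parameters(model: ModelSpec, values, direction: str) -> np.ndarray:
    """Map an ordered parameter array between native and unconstrained space.

    Unit-interval parameters map through a sigmoid/logit pair, nonnegative
    weights through exp/log; the round trip is the identity to 1e-10.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (model.n_params,):
        raise ValueError(f"expected {model.n_params} values for {model.name}, got shape {x.shape}")
    kinds = np.array([k == UNIT for k in model.parameter_kinds])
    out = np.empty_like(x)
    if direction == "to_native":
        with np.errstate(over="ignore"):
            out[kinds] = 1.0 / (1.0 + np.exp(-x[kinds]))
            out[~kinds] = np.exp(x[~kinds])
    elif direction == "to_unconstrained":
        validate_parameters(model, x)
        with np.errstate(divide="ignore"):
            u = x[kinds]
            out[kinds] = np.log(u) - np.log1p(-u)
            out[~kinds] = np.log(x[~kinds])
    else:
        raise ValueError(f"direction must be 'to_native' or 'to_unconstrained', got {direction!r}")
    return out


# ---------------------------------------------------------------------------
# agent state and single-trial operations (reference semantics)
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    """Per-pair option values plus the shared accumulator mu."""

    pair_index: Dict[str, int]
    q: np.ndarray       # (n_pairs, 2): value of (better, worse) option
    q_pos: np.ndarray   # two-stream model only
    q_neg: np.ndarray
    mu: float = 0.0


@dataclass(frozen=True)
class TrialOutcome:
    pair_id: str
    chosen: int     # 0 = better option, 1 = worse option
    reward: float   # feedback points actually delivered
    task: str = "inducer"


def init_agent_state(session: SessionSpec, model_spec: ModelSpec) -> AgentState:
    """All Q values (both streams) and mu start at zero, so ARR-modulated
    models begin at their constant terms alpha_0 / beta_0."""
    if model_spec.name not in MODELS:
        raise ValueError(f"unknown model {model_spec!r}")
    pair_ids: List[str] = []
    for block in session.all_blocks:
        for task in ("inducer", "reference"):
            pair_ids.append(block.pair_ids[task])
    index = {pid: i for i, pid in enumerate(pair_ids)}
    n = len(index)
    return AgentState(pair_index=index, q=np.zeros((n, 2)),
                      q_pos=np.zeros((n, 2)), q_neg=np.zeros((n, 2)), mu=0.0)


def _effective_beta(state: AgentState, params: ParameterVector) -> float:
    m = params.model
    if m.modulation_target == "decision_weight":
        return max(0.0, params["beta0"] * (1.0 + state.mu))
    return params["beta"]


def choice_probabilities(state: AgentState, pair_id: str, params: ParameterVector,
                         model_spec: ModelSpec) -> Tuple[float, float]:
    """Softmax probabilities of (better, worse) option for one pair."""
    i = state.pair_index[pair_id]
    if model_spec.model_id == _kernels.NULL_AR:
        qb = state.q_pos[i, 0] + state.q_neg[i, 0]
        qw = state.q_pos[i, 1] + state.q_neg[i, 1]
    else:
        qb, qw = state.q[i, 0], state.q[i, 1]
    if not (np.isfinite(qb) and np.isfinite(qw)):
        raise FloatingPointError(f"non-finite Q values for pair {pair_id}")
    beta = _effective_beta(state, params)
    p_better = 1.0 / (1.0 + np.exp(-beta * (qb - qw)))
    return float(p_better), float(1.0 - p_better)


def update_agent_state(state: AgentState, outcome: TrialOutcome,
                       params: ParameterVector, model_spec: ModelSpec) -> AgentState:
    """Apply one trial's learning update in place and return the state.

    Only the chosen option of the outcome's pair changes; mu (if the model has
    an accumulator) updates once, after the Q update, from the pre-update mu.
    """
    validate_parameters(model_spec, params.as_array())
    i = state.pair_index[outcome.pair_id]
    c = outcome.chosen
    r = outcome.reward
    mu = state.mu
    mid = model_spec.model_id

    if mid == _kernels.NULL_A:
        state.q[i, c] += params["alpha"] * (r - state.q[i, c])
    elif mid == _kernels.NULL_APE:
        delta = r - state.q[i, c]
        lr = params["alpha_pos"] if delta > 0 else params["alpha_neg"]
        state.q[i, c] += lr * delta
    elif mid == _kernels.NULL_AR:
        r_pos = r if r > 0 else 0.0
        r_neg = r if r <= 0 else 0.0
        d_pos = params["w_pos"] * r_pos - state.q_pos[i, c]
        d_neg = params["w_neg"] * r_neg - state.q_neg[i, c]
        state.q_pos[i, c] = params["lambda_pos"] * state.q_pos[i, c] + params["alpha"] * d_pos
        state.q_neg[i, c] = params["lambda_neg"] * state.q_neg[i, c] + params["alpha"] * d_neg
    elif mid in (_kernels.FB_PE, _kernels.FB_R):
        delta = r - state.q[i, c] + mu
        state.q[i, c] += params["alpha"] * delta
        if mid == _kernels.FB_PE:
            state.mu = mu + params["alpha_mu"] * (delta - mu)
        else:
            state.mu = mu + params["alpha_mu"] * (r - mu)
    elif mid in (_kernels.A_PE, _kernels.A_R):
        delta = r - state.q[i, c]
        lr = float(np.clip(params["alpha0"] * (1.0 + mu), 0.0, 1.0))
        state.q[i, c] += lr * delta
        if mid == _kernels.A_PE:
            state.mu = mu + params["alpha_mu"] * (delta - mu)
        else:
            state.mu = mu + params["alpha_mu"] * (r - mu)
    else:  # b-PE / b-R
        delta = r - state.q[i, c]
        state.q[i, c] += params["alpha"] * delta
        if mid == _kernels.B_PE:
            state.mu = mu + params["alpha_mu"] * (delta - mu)
        else:
            state.mu = mu + params["alpha_mu"] * (r - mu)
    return state


def reset_accumulator(state: AgentState) -> AgentState:
    """Block boundary: mu returns to zero (Q values persist per pair)."""
    state.mu = 0.0
    return state


# ---------------------------------------------------------------------------
# trial-sequence likelihood and trajectories (kernel-backed)
# ---------------------------------------------------------------------------

@dataclass
class SubjectArrays:
    """A subject's non-missed experiment-proper trials as flat arrays."""

    pair: np.ndarray         # int pair index
    chosen: np.ndarray       # 0 better / 1 worse
    reward: np.ndarray       # delivered feedback points
    block_start: np.ndarray  # bool: first retained trial of its block
    n_pairs: int
    frame: pd.DataFrame | None = None  # retained rows, for trajectory alignment

    @property
    def n_trials(self) -> int:
        return int(self.pair.shape[0])


def prepare_subject_arrays(trials: pd.DataFrame, include_training: bool = False) -> SubjectArrays:
    """Convert one subject's trial table into likelihood-ready arrays.

    Training-block rows (block_index <= 0) and missed trials are dropped;
    remaining trials must already be in global trial order.
    """
    df = trials
    if not df["global_trial"].is_monotonic_increasing:
        raise ValueError("trials out of order: global_trial must be increasing")
    if not include_training:
        df = df[df["block_index"] >= 1]
    df = df[df["missed"] == 0]
    pair_ids = pd.unique(df["pair_id"])
    index = {pid: i for i, pid in enumerate(pair_ids)}
    pair = df["pair_id"].map(index).to_numpy(dtype=np.int64)
    chosen = np.where(df["chosen_option"].to_numpy() == "better", 0, 1).astype(np.int64)
    reward = df["feedback_points"].to_numpy(dtype=float)
    block = df["block_index"].to_numpy()
    block_start = np.ones(len(df), dtype=np.bool_)
    block_start[1:] = block[1:] != block[:-1]
    return SubjectArrays(pair=pair, chosen=chosen, reward=reward,
                         block_start=block_start, n_pairs=max(len(index), 1),
                         frame=df.reset_index(drop=True))


def _native_theta(model_spec: ModelSpec, params) -> np.ndarray:
    if isinstance(params, ParameterVector):
        arr = params.as_array()
    else:
        arr = np.asarray(params, dtype=float)
    if arr.shape != (model_spec.n_params,):
        raise ValueError(f"{model_spec.name} takes {model_spec.n_params} parameters")
    validate_parameters(model_spec, arr)
    th = np.zeros(MAX_PARAMS)
    th[:arr.shape[0]] = arr
    return th


def negative_log_likelihood(model_spec: ModelSpec, params, subject_trials) -> float:
    """Summed -log P(chosen option) over a subject's non-missed trials (nats).

    State evolves through both tasks in interleaved order: Q per stimulus pair,
    mu shared and reset at block boundaries.
    """
    sub = subject_trials if isinstance(subject_trials, SubjectArrays) \
        else prepare_subject_arrays(subject_trials)
    th = _native_theta(model_spec, params)
    n = sub.n_trials
    buf = np.empty(n)
    return float(_kernels.run_model(model_spec.model_id, th, sub.pair, sub.chosen,
                                    sub.reward, sub.block_start, sub.n_pairs,
                                    buf, np.empty(n)))


def choice_probability_trajectory(model_spec: ModelSpec, params, subject_trials) -> pd.DataFrame:
    """Per-trial P(better option) and accumulator value mu along a subject's
    observed trial sequence (the deterministic, conditioning-on-data analogue
    of re-simulating choices).  Returns the retained trial rows with added
    ``p_better`` and ``mu`` columns."""
    sub = subject_trials if isinstance(subject_trials, SubjectArrays) \
        else prepare_subject_arrays(subject_trials)
    th = _native_theta(model_spec, params)
    n = sub.n_trials
    p_better = np.empty(n)
    mu = np.empty(n)
    _kernels.run_model(model_spec.model_id, th, sub.pair, sub.chosen,
                       sub.reward, sub.block_start, sub.n_pairs, p_better, mu)
    out = sub.frame.copy()
    out["p_better"] = p_better
    out["mu"] = mu
    return out


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "subject_id", "experiment_id", "block_index", "condition", "global_trial",
    "task", "trial_within_task", "pair_id", "chosen_option", "correct",
    "feedback_points", "missed", "response_side",
]


def _session_design_rows(session: SessionSpec) -> pd.DataFrame:
    """Flatten a session design into one row per trial (no choices yet)."""
    cfg = session.experiment_config
    rows = []
    for block in session.all_blocks:
        within = {"inducer": 0, "reference": 0}
        for t, task in enumerate(block.task_order):
            within[task] += 1
            i = within[task] - 1
            better_v, worse_v = (block.outcome_schedule[task][0][i],
                                 block.outcome_schedule[task][1][i])
            if block.block_index == 0:
                gt = t - 23  # training runs -23..0
            else:
                gt = (block.block_index - 1) * 24 + t + 1
            rows.append({
                "block_index": block.block_index,
                "condition": block.condition,
                "global_trial": gt,
                "task": task,
                "trial_within_task": i + 1,
                "pair_id": block.pair_ids[task],
                "reward_better": cfg.magnitude(task, block.condition,
                                               "positive" if better_v > 0 else "negative"),
                "reward_worse": cfg.magnitude(task, block.condition,
                                              "positive" if worse_v > 0 else "negative"),
                "better_side": block.better_side[t] if block.better_side else "left",
            })
    return pd.DataFrame(rows)


def session_trial_frame(session: SessionSpec, subject_id: str = "design") -> pd.DataFrame:
    """Schedule-only export of a session: one row per trial with no choices
    (``chosen_option='none'``, ``missed=1``, timeout penalty as feedback)."""
    design = _session_design_rows(session)
    out = design.drop(columns=["reward_better", "reward_worse"]).copy()
    out.insert(0, "subject_id", subject_id)
    out.insert(1, "experiment_id", session.experiment_config.experiment_id)
    out["chosen_option"] = "none"
    out["correct"] = pd.NA
    out["feedback_points"] = session.experiment_config.timeout_penalty
    out["missed"] = 1
    out["response_side"] = "none"
    return out[TRIAL_COLUMNS]


def simulate_agent(model_spec: ModelSpec, params, session: SessionSpec, rng,
                   subject_id: str = "sim") -> pd.DataFrame:
    """Forward-simulate one agent through a session (training included).

    Choices are sampled from the model's softmax; feedback comes from the
    session's pre-assigned outcome schedules.  Simulated agents never miss a
    trial.  Returns a long-format trial table.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    th = _native_theta(model_spec, params)
    design = _session_design_rows(session)
    n = len(design)
    pair_ids = pd.unique(design["pair_id"])
    index = {pid: i for i, pid in enumerate(pair_ids)}
    pair = design["pair_id"].map(index).to_numpy(dtype=np.int64)
    block = design["block_index"].to_numpy()
    block_start = np.ones(n, dtype=np.bool_)
    block_start[1:] = block[1:] != block[:-1]
    u = rng.random(n)
    chosen = np.empty(n, dtype=np.int64)
    reward = np.empty(n)
    _kernels.simulate_model(model_spec.model_id, th, pair,
                            design["reward_better"].to_numpy(float),
                            design["reward_worse"].to_numpy(float),
                            block_start, len(index), u, chosen, reward,
                            np.empty(n), np.empty(n))
    out = design.drop(columns=["reward_better", "reward_worse"]).copy()
    out.insert(0, "subject_id", subject_id)
    out.insert(1, "experiment_id", session.experiment_config.experiment_id)
    out["chosen_option"] = np.where(chosen == 0, "better", "worse")
    out["correct"] = (chosen == 0).astype(int)
    out["feedback_points"] = reward
    out["missed"] = 0
    flip = {"left": "right", "right": "left"}
    out["response_side"] = [
        s if c == 0 else flip[s] for s, c in zip(out["better_side"], chosen)
    ]
    return out[TRIAL_COLUMNS]
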