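import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import arrlearn as al


@pytest.fixture(scope="session")
def session_exp1():
    return al.generate_session(al.experiment_config(1), np.random.default_rng(7))


@pytest.fixture(scope="session")
def fbr():
    return al.get_model("FB-R")


@pytest.fixture(scope="session")
def fbr_trials(session_exp1, fbr):
    """One simulated subject's trial table under the headline model."""
    pv = al.make_parameters(fbr, alpha=0.4, alpha_mu=0.7, beta=2.5)
    return al.simulate_agent(fbr, pv, session_exp1, np.random.default_rng(3))


def random_trials(rng, n_trials=48, n_pairs=4, n_blocks=2, rewards=(1.0, -1.0, 3.0, -3.0, 0.0)):
    """Small random trial list in both the oracle's and the package's formats."""
    import pandas as pd

    rows, olist = [], []
    per_block = n_trials // n_blocks
    for t in range(n_trials):
        block = 1 + t // per_block
        pair = int(rng.integers(n_pairs))
        chosen = int(rng.integers(2))
        reward = float(rng.choice(rewards))
        olist.append({"pair": pair, "chosen": chosen, "reward": reward, "block": block})
        rows.append({
            "subject_id": "S", "experiment_id": 1, "block_index": block,
            "condition": "medium", "global_trial": t + 1,
            "task": "inducer" if t % 2 == 0 else "reference",
            "trial_within_task": 1 + (t // 2) % 12, "pair_id": f"P{pair}",
            "chosen_option": "better" if chosen == 0 else "worse",
            "correct": 1 - chosen, "feedback_points": reward, "missed": 0,
            "response_side": "left",
        })
    return olist, pd.DataFrame(rows)


def random_native_params(model, rng):
    values = {}
    for name, kind in zip(model.parameter_names, model.parameter_kinds):
        if kind == "unit":
            values[name] = float(rng.uniform(0.05, 0.95))
        else:
            values[name] = float(rng.uniform(0.1, 8.0))
    return al.make_parameters(model, **values)
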