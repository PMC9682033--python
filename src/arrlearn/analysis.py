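"""Behavioral summaries and statistics on trial-table cohorts.

Learning performance is the hit rate (proportion of better-option choices)
over the last third of a task-block's trials, i.e. within-task trials 9-12,
averaged over the five blocks of each condition.  The headline design question
is whether reference-task performance drops when the interleaved inducer task
pays off rarely (low average reward rate), assessed with a mixed
(split-plot) ANOVA -- between-subject factor Experiment, within-subject factor
Condition -- followed by paired t-tests with Cohen's d on the paired
differences.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .models import ModelSpec, choice_probability_trajectory
from .task import CONDITIONS

LATE_TRIALS = (9, 12)  # within-task trial window defining learning performance


def _proper(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["block_index"] >= 1]


def learning_performance(cohort, task: str | None = None) -> pd.DataFrame:
    """Per subject x condition x task mean hit rate over within-task trials
    9-12 (non-missed trials only), in long format with columns
    subject_id, experiment_id, task, condition, hit_rate.

    A subject/condition/task cell whose 20 relevant trials were all missed
    comes out as NaN (flagged missing).
    """
    trials = _proper(cohort.trials if hasattr(cohort, "trials") else cohort)
    late = trials[(trials["trial_within_task"] >= LATE_TRIALS[0])
                  & (trials["trial_within_task"] <= LATE_TRIALS[1])]
    late = late[late["missed"] == 0].copy()
    late["correct"] = late["correct"].astype(float)
    grouped = (late.groupby(["subject_id", "experiment_id", "task", "condition"],
                            observed=True)["correct"]
               .mean().rename("hit_rate").reset_index())
    # reinstate all-missed cells as NaN
    all_cells = (trials[["subject_id", "experiment_id", "task", "condition"]]
                 .drop_duplicates())
    out = all_cells.merge(grouped, how="left",
                          on=["subject_id", "experiment_id", "task", "condition"])
    if task is not None:
        out = out[out["task"] == task].reset_index(drop=True)
    return out.sort_values(["subject_id", "task", "condition"]).reset_index(drop=True)


def learning_curves(cohort) -> pd.DataFrame:
    """Mean hit rate (and SEM over subjects) at each within-task trial index
    1-12, per task and condition."""
    trials = _proper(cohort.trials if hasattr(cohort, "trials") else cohort)
    ok = trials[trials["missed"] == 0].copy()
    ok["correct"] = ok["correct"].astype(float)
    per_subject = (ok.groupby(["task", "condition", "trial_within_task", "subject_id"],
                              observed=True)["correct"].mean())
    agg = per_subject.groupby(["task", "condition", "trial_within_task"]).agg(
        hit_rate="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
    return agg.reset_index()


def _reference_wide(perf_table: pd.DataFrame, task: str = "reference") -> pd.DataFrame:
    sub = perf_table[perf_table["task"] == task]
    wide = sub.pivot_table(index=["subject_id", "experiment_id"],
                           columns="condition", values="hit_rate")
    return wide.reset_index()


def mixed_anova_condition_experiment(perf_table: pd.DataFrame,
                                     task: str = "reference") -> pd.DataFrame:
    """Split-plot ANOVA of hit rate: between-subject Experiment, within-subject
    Condition.  Subjects with incomplete condition cells are dropped with a
    warning.  Returns the ANOVA table (SS, df, MS, F, p, partial eta squared).
    """
    wide = _reference_wide(perf_table, task)
    complete = wide.dropna(subset=list(CONDITIONS))
    if len(complete) < len(wide):
        import warnings
        warnings.warn(f"dropping {len(wide) - len(complete)} subjects with missing cells")
    long = complete.melt(id_vars=["subject_id", "experiment_id"],
                         value_vars=list(CONDITIONS),
                         var_name="condition", value_name="hit_rate")
    aov = pg.mixed_anova(data=long, dv="hit_rate", within="condition",
                         subject="subject_id", between="experiment_id")
    return aov.rename(columns={"Source": "effect", "p-unc": "p", "p_unc": "p"})


def pairwise_condition_tests(perf_table: pd.DataFrame,
                             task: str = "reference") -> pd.DataFrame:
    """Paired two-tailed t-tests between conditions with 95% CI of the mean
    difference and Cohen's d = mean(diff) / SD(diff)."""
    wide = _reference_wide(perf_table, task).dropna(subset=list(CONDITIONS))
    if len(wide) < 2:
        raise ValueError("need at least 2 complete subjects for paired tests")
    rows = []
    for a, b in (("low", "medium"), ("low", "high"), ("medium", "high")):
        diff = wide[a].to_numpy(float) - wide[b].to_numpy(float)
        n = diff.shape[0]
        sd = diff.std(ddof=1)
        if sd == 0.0:  # zero-noise columns: degenerate CI at the shift
            t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            p = 1.0 if diff.mean() == 0 else 0.0
            half, d = 0.0, 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
            se = sd / np.sqrt(n)
            half = stats.t.ppf(0.975, n - 1) * se
            d = diff.mean() / sd
        rows.append({"contrast": f"{a} vs {b}", "t": float(t), "df": n - 1,
                     "ci95_low": diff.mean() - half, "ci95_high": diff.mean() + half,
                     "p": float(p), "cohen_d": float(d), "mean_diff": diff.mean()})
    return pd.DataFrame(rows)


def fit_quality_correlations(actual_perf: pd.DataFrame,
                             fitted_perf: pd.DataFrame,
                             task: str = "reference") -> pd.DataFrame:
    """Pearson correlations between actual and model-fitted learning
    performance across subjects: overall mean, and each pairwise condition
    difference."""
    a = _reference_wide(actual_perf, task).set_index("subject_id")
    f = _reference_wide(fitted_perf, task).set_index("subject_id")
    if set(a.index) != set(f.index):
        raise ValueError("actual and fitted tables cover different subjects")
    f = f.loc[a.index]
    rows = []

    def corr(label, x, y):
        r, p = stats.pearsonr(x, y)
        rows.append({"measure": label, "r": float(r), "p": float(p), "n": len(x)})

    conds = list(CONDITIONS)
    corr("overall", a[conds].mean(axis=1), f[conds].mean(axis=1))
    for c1, c2 in (("low", "medium"), ("low", "high"), ("medium", "high")):
        corr(f"{c1} vs {c2}", a[c1] - a[c2], f[c1] - f[c2])
    return pd.DataFrame(rows)


def model_fitted_performance(cohort, model_spec: ModelSpec,
                             subject_params: pd.DataFrame) -> pd.DataFrame:
    """Model-fitted hit rates: average P(better option) over within-task trials
    9-12 along each subject's observed trial sequence at their fitted
    parameters (the deterministic, low-variance analogue of re-simulating
    choices).  ``subject_params`` has one row per subject (native space).
    Output matches :func:`learning_performance`'s long format."""
    trials = cohort.trials if hasattr(cohort, "trials") else cohort
    frames = []
    for sid, df in trials.groupby("subject_id", sort=True):
        if sid not in subject_params.index:
            continue
        theta = subject_params.loc[sid, list(model_spec.parameter_names)].to_numpy(float)
        traj = choice_probability_trajectory(model_spec, theta, df)
        late = traj[(traj["trial_within_task"] >= LATE_TRIALS[0])
                    & (traj["trial_within_task"] <= LATE_TRIALS[1])]
        agg = (late.groupby(["experiment_id", "task", "condition"], observed=True)
               ["p_better"].mean().rename("hit_rate").reset_index())
        agg.insert(0, "subject_id", sid)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def arr_trajectories(cohort, model_spec: ModelSpec,
                     subject_params: pd.DataFrame) -> pd.DataFrame:
    """Mean fitted accumulator value mu at each reference-task within-task
    trial, per condition (averaged over subjects and blocks)."""
    trials = cohort.trials if hasattr(cohort, "trials") else cohort
    frames = []
    for sid, df in trials.groupby("subject_id", sort=True):
        if sid not in subject_params.index:
            continue
        theta = subject_params.loc[sid, list(model_spec.parameter_names)].to_numpy(float)
        traj = choice_probability_trajectory(model_spec, theta, df)
        ref = traj[traj["task"] == "reference"]
        frames.append(ref.groupby(["condition", "trial_within_task"], observed=True)
                      ["mu"].mean().rename(sid))
    stacked = pd.concat(frames, axis=1)
    out = stacked.mean(axis=1).rename("mu").reset_index()
    out["sem"] = stacked.sem(axis=1).to_numpy()
    return out
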