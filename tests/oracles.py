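"""Independent straight-line oracles used to cross-check the package.

Deliberately naive re-derivations: explicit per-trial loops over dictionaries,
one branch per model, no shared code with the package's kernels.
"""

import math

import numpy as np


def oracle_nll(model_name, params, trials):
    """Negative log-likelihood of a trial sequence.

    ``trials``: list of dicts with keys pair (hashable), chosen (0 better /
    1 worse), reward (float), block (int).  ``params``: dict of native values.
    """
    q = {}
    qpos = {}
    qneg = {}
    mu = 0.0
    prev_block = None
    nll = 0.0
    for tr in trials:
        if tr["block"] != prev_block:
            mu = 0.0
            prev_block = tr["block"]
        key = tr["pair"]
        if key not in q:
            q[key] = [0.0, 0.0]
            qpos[key] = [0.0, 0.0]
            qneg[key] = [0.0, 0.0]
        c = tr["chosen"]
        r = tr["reward"]

        if model_name in ("b-PE", "b-R"):
            beta = params["beta0"] * (1.0 + mu)
            if beta < 0:
                beta = 0.0
        else:
            beta = params["beta"]
        if model_name == "null-aR":
            v0 = qpos[key][0] + qneg[key][0]
            v1 = qpos[key][1] + qneg[key][1]
        else:
            v0, v1 = q[key]
        e0 = math.exp(beta * v0)
        e1 = math.exp(beta * v1)
        p_chosen = (e0 if c == 0 else e1) / (e0 + e1)
        nll -= math.log(p_chosen)

        if model_name == "null-a":
            q[key][c] = q[key][c] + params["alpha"] * (r - q[key][c])
        elif model_name == "null-aPE":
            delta = r - q[key][c]
            a = params["alpha_pos"] if delta > 0 else params["alpha_neg"]
            q[key][c] = q[key][c] + a * delta
        elif model_name == "null-aR":
            rp = r if r > 0 else 0.0
            rn = r if r <= 0 else 0.0
            dp = params["w_pos"] * rp - qpos[key][c]
            dn = params["w_neg"] * rn - qneg[key][c]
            qpos[key][c] = params["lambda_pos"] * qpos[key][c] + params["alpha"] * dp
            qneg[key][c] = params["lambda_neg"] * qneg[key][c] + params["alpha"] * dn
        elif model_name in ("FB-PE", "FB-R"):
            delta = r - q[key][c] + mu
            q[key][c] = q[key][c] + params["alpha"] * delta
            if model_name == "FB-PE":
                mu = mu + params["alpha_mu"] * (delta - mu)
            else:
                mu = mu + params["alpha_mu"] * (r - mu)
        elif model_name in ("a-PE", "a-R"):
            delta = r - q[key][c]
            a = params["alpha0"] * (1.0 + mu)
            a = min(max(a, 0.0), 1.0)
            q[key][c] = q[key][c] + a * delta
            if model_name == "a-PE":
                mu = mu + params["alpha_mu"] * (delta - mu)
            else:
                mu = mu + params["alpha_mu"] * (r - mu)
        elif model_name in ("b-PE", "b-R"):
            delta = r - q[key][c]
            q[key][c] = q[key][c] + params["alpha"] * delta
            if model_name == "b-PE":
                mu = mu + params["alpha_mu"] * (delta - mu)
            else:
                mu = mu + params["alpha_mu"] * (r - mu)
        else:
            raise ValueError(model_name)
    return nll


def oracle_mixed_anova(wide, between):
    """Brute-force sums-of-squares for a balanced split-plot design.

    ``wide``: 2-D array (subjects x within-levels); ``between``: group label
    per subject.  Returns dict of SS / df / F for the between factor, the
    within factor, and their interaction.
    """
    y = np.asarray(wide, float)
    groups = np.asarray(between)
    n, k = y.shape
    labels = sorted(set(groups.tolist()))
    g = len(labels)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {lab: y[groups == lab].mean() for lab in labels}
    cond_means = y.mean(axis=0)
    cell_means = {lab: y[groups == lab].mean(axis=0) for lab in labels}

    ss_between = sum(k * (groups == lab).sum() * (group_means[lab] - grand) ** 2
                     for lab in labels)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_error_between = ss_subj - ss_between
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_inter = 0.0
    for lab in labels:
        n_g = (groups == lab).sum()
        for j in range(k):
            ss_inter += n_g * (cell_means[lab][j] - group_means[lab]
                               - cond_means[j] + grand) ** 2
    ss_total = np.sum((y - grand) ** 2)
    ss_error_within = ss_total - ss_subj - ss_cond - ss_inter

    df_b, df_eb = g - 1, n - g
    df_w, df_ew = k - 1, (k - 1) * (n - g)
    out = {
        "between": (ss_between, df_b, (ss_between / df_b) / (ss_error_between / df_eb)),
        "within": (ss_cond, df_w, (ss_cond / df_w) / (ss_error_within / df_ew)),
        "interaction": (ss_inter, df_w * df_b,
                        (ss_inter / (df_w * df_b)) / (ss_error_within / df_ew)),
        "error_between": (ss_error_between, df_eb),
        "error_within": (ss_error_within, df_ew),
    }
    return out


def oracle_paired_t(a, b):
    """Textbook paired t-test: t, df, 95% CI of the mean difference, Cohen's d."""
    from scipy import stats as st

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.shape[0]
    mean = d.mean()
    sd = math.sqrt(np.sum((d - mean) ** 2) / (n - 1))
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2 * st.t.sf(abs(t), n - 1)
    half = st.t.ppf(0.975, n - 1) * se
    return t, n - 1, (mean - half, mean + half), p, mean / sd
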