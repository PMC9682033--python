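"""Jitted inner loops for trial-sequence likelihoods and state trajectories.

One kernel handles the whole model family, dispatching on an integer model id
(the index into :data:`arrlearn.models.MODEL_NAMES`).  Parameters arrive as a
flat native-space array padded to length 6.  The kernel walks the interleaved
trial sequence once, maintaining per-pair Q values and the shared average
accumulator mu, and writes per-trial quantities into the output buffers:

- ``p_better[t]``: softmax probability of the better option before the update
- ``mu_out[t]``: the accumulator value entering trial t (after any block reset)

and returns the summed negative log-likelihood of the chosen options.

mu resets to 0 at every block boundary (``block_start``), updates once per
non-missed trial of either task, and is read *before* its own update wherever
it enters a delta, learning rate or decision weight.
"""

import numpy as np
from numba import njit

# model ids, in registry order
NULL_A = 0
NULL_APE = 1
NULL_AR = 2
FB_PE = 3
A_PE = 4
B_PE = 5
FB_R = 6
A_R = 7
B_R = 8


@njit(cache=True)
def run_model(mid, th, pair, chosen, reward, block_start, n_pairs,
              p_better, mu_out):  # pragma: no cover - exercised via wrappers
    q = np.zeros((n_pairs, 2))
    qpos = np.zeros((n_pairs, 2))
    qneg = np.zeros((n_pairs, 2))
    mu = 0.0
    nll = 0.0
    n = pair.shape[0]
    for t in range(n):
        if block_start[t]:
            mu = 0.0
        mu_out[t] = mu
        p = pair[t]
        c = chosen[t]
        r = reward[t]

        # effective decision weight
        if mid == B_PE or mid == B_R:
            beta = th[2] * (1.0 + mu)
            if beta < 0.0:
                beta = 0.0
        elif mid == NULL_A or mid == FB_PE or mid == A_PE or mid == FB_R or mid == A_R:
            beta = th[2] if (mid != NULL_A) else th[1]
        elif mid == NULL_APE:
            beta = th[2]
        else:  # NULL_AR
            beta = th[5]

        if mid == NULL_AR:
            dq = (qpos[p, 0] + qneg[p, 0]) - (qpos[p, 1] + qneg[p, 1])
        else:
            dq = q[p, 0] - q[p, 1]
        x = beta * dq
        pb = 1.0 / (1.0 + np.exp(-x))
        p_better[t] = pb
        # -log P(chosen) = log(1 + exp(-x_c)), evaluated stably
        xc = x if c == 0 else -x
        if xc < -700.0:
            nll -= xc
        else:
            nll += np.log1p(np.exp(-xc))

        # learning update (chosen option only); delta uses pre-update mu
        if mid == NULL_A:
            delta = r - q[p, c]
            q[p, c] += th[0] * delta
        elif mid == NULL_APE:
            delta = r - q[p, c]
            lr = th[0] if delta > 0.0 else th[1]
            q[p, c] += lr * delta
        elif mid == NULL_AR:
            alpha, lpos, lneg, wpos, wneg = th[0], th[1], th[2], th[3], th[4]
            rpos = r if r > 0.0 else 0.0
            rneg = r if r <= 0.0 else 0.0
            dpos = wpos * rpos - qpos[p, c]
            dneg = wneg * rneg - qneg[p, c]
            qpos[p, c] = lpos * qpos[p, c] + alpha * dpos
            qneg[p, c] = lneg * qneg[p, c] + alpha * dneg
        elif mid == FB_PE or mid == FB_R:
            delta = r - q[p, c] + mu
            q[p, c] += th[0] * delta
            if mid == FB_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
        elif mid == A_PE or mid == A_R:
            delta = r - q[p, c]
            lr = th[0] * (1.0 + mu)
            if lr < 0.0:
                lr = 0.0
            elif lr > 1.0:
                lr = 1.0
            q[p, c] += lr * delta
            if mid == A_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
        else:  # B_PE or B_R
            delta = r - q[p, c]
            q[p, c] += th[0] * delta
            if mid == B_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
    return nll


@njit(cache=True)
def simulate_model(mid, th, pair, reward_better, reward_worse, block_start,
                   n_pairs, u, chosen, reward,
                   p_better, mu_out):  # pragma: no cover - exercised via wrappers
    """Forward-simulate choices: option sampled against the uniform draws ``u``,
    feedback read from the pre-assigned per-option outcome arrays.  Fills
    ``chosen`` and ``reward`` in place and shares the state-evolution code path
    contract of :func:`run_model` (verified in tests)."""
    q = np.zeros((n_pairs, 2))
    qpos = np.zeros((n_pairs, 2))
    qneg = np.zeros((n_pairs, 2))
    mu = 0.0
    n = pair.shape[0]
    for t in range(n):
        if block_start[t]:
            mu = 0.0
        mu_out[t] = mu
        p = pair[t]

        if mid == B_PE or mid == B_R:
            beta = th[2] * (1.0 + mu)
            if beta < 0.0:
                beta = 0.0
        elif mid == NULL_A:
            beta = th[1]
        elif mid == NULL_AR:
            beta = th[5]
        else:
            beta = th[2]

        if mid == NULL_AR:
            dq = (qpos[p, 0] + qneg[p, 0]) - (qpos[p, 1] + qneg[p, 1])
        else:
            dq = q[p, 0] - q[p, 1]
        pb = 1.0 / (1.0 + np.exp(-beta * dq))
        p_better[t] = pb
        c = 0 if u[t] < pb else 1
        chosen[t] = c
        r = reward_better[t] if c == 0 else reward_worse[t]
        reward[t] = r

        if mid == NULL_A:
            q[p, c] += th[0] * (r - q[p, c])
        elif mid == NULL_APE:
            delta = r - q[p, c]
            lr = th[0] if delta > 0.0 else th[1]
            q[p, c] += lr * delta
        elif mid == NULL_AR:
            alpha, lpos, lneg, wpos, wneg = th[0], th[1], th[2], th[3], th[4]
            rpos = r if r > 0.0 else 0.0
            rneg = r if r <= 0.0 else 0.0
            qpos[p, c] = lpos * qpos[p, c] + alpha * (wpos * rpos - qpos[p, c])
            qneg[p, c] = lneg * qneg[p, c] + alpha * (wneg * rneg - qneg[p, c])
        elif mid == FB_PE or mid == FB_R:
            delta = r - q[p, c] + mu
            q[p, c] += th[0] * delta
            if mid == FB_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
        elif mid == A_PE or mid == A_R:
            delta = r - q[p, c]
            lr = th[0] * (1.0 + mu)
            if lr < 0.0:
                lr = 0.0
            elif lr > 1.0:
                lr = 1.0
            q[p, c] += lr * delta
            if mid == A_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
        else:
            delta = r - q[p, c]
            q[p, c] += th[0] * delta
            if mid == B_PE:
                mu += th[1] * (delta - mu)
            else:
                mu += th[1] * (r - mu)
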