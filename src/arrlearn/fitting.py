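"""Hierarchical Bayesian random-effects fitting and model comparison.

An empirical-Bayes EM over subjects and models:

- E-step: each subject x model is fit by MAP under the current Gaussian group
  prior in unconstrained parameter space (multi-start quasi-Newton), and its
  marginal likelihood approximated by a Laplace integral around the MAP.
  Responsibilities (posterior probability that model k generated subject n's
  choices) follow from the evidences and the current model frequencies.
- M-step: responsibility-weighted group means/variances per model, and a
  Dirichlet posterior over model frequencies.

From the Dirichlet posterior we compute exceedance probabilities (EP, the
probability that a model is the most frequent in the population, by Monte
Carlo), the Bayes omnibus risk (BOR, posterior probability that all models are
equally frequent), and protected exceedance probabilities
PXP_k = EP_k * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .models import (ModelSpec, SubjectArrays, negative_log_likelihood,
                     prepare_subject_arrays, transform_parameters)

log = logging.getLogger(__name__)

LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class FitConfig:
    """Knobs of the hierarchical fit (all deterministic given ``seed``)."""

    prior_mean: float = 0.0
    prior_var: float = 6.25        # weakly informative in unconstrained space
    dirichlet_prior: float = 1.0   # symmetric concentration over models
    n_restarts: int = 10           # prior draws per subject-model, first E-step
    warm_restarts: int = 1         # fresh draws on later E-steps (plus warm start)
    tol: float = 1e-4
    max_iter: int = 50
    mc_samples: int = 100_000      # Dirichlet draws for EP
    var_floor: float = 1e-2        # group-variance floor (unconstrained space)
    hessian_ridge: float = 1e-6
    seed: int = 0


@dataclass
class SubjectModelFit:
    """One subject x one model: MAP fit and Laplace evidence."""

    theta: np.ndarray            # MAP, unconstrained space
    log_likelihood: float        # at MAP (nats, negated NLL)
    log_evidence: float          # Laplace approximation of the marginal likelihood
    posterior_var: np.ndarray    # diag of inverse Hessian at MAP
    converged: bool = True

    def native(self, model: ModelSpec) -> np.ndarray:
        return transform_parameters(model, self.theta, "to_native")


@dataclass
class GroupFit:
    """Group-level output of :func:`hbi_fit`."""

    models: List[ModelSpec]
    subject_ids: List[str]
    fits: Dict[str, Dict[str, SubjectModelFit]]  # subject -> model name -> fit
    responsibilities: pd.DataFrame               # subjects x model names
    group_mean: Dict[str, np.ndarray]            # unconstrained space
    group_var: Dict[str, np.ndarray]
    dirichlet_alpha: np.ndarray
    frequencies: np.ndarray
    exceedance: np.ndarray
    bor: float
    pxp: np.ndarray
    trace: List[dict] = field(default_factory=list)

    @property
    def model_names(self) -> List[str]:
        return [m.name for m in self.models]

    def best_model(self) -> str:
        return self.model_names[int(np.argmax(self.pxp))]

    def subject_parameters(self, model: ModelSpec) -> pd.DataFrame:
        """Fitted native-space parameters of one model, one row per subject."""
        rows = {sid: self.fits[sid][model.name].native(model) for sid in self.subject_ids}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(model.parameter_names))

    def group_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_names,
            "frequency": self.frequencies,
            "exceedance_probability": self.exceedance,
            "protected_exceedance_probability": self.pxp,
            "bor": self.bor,
        })


# ---------------------------------------------------------------------------
# subject-level Laplace fit
# ---------------------------------------------------------------------------

def _neg_log_posterior(x, model, sub, m, v):
    native = transform_parameters(model, x, "to_native")
    if not np.all(np.isfinite(native)):  # line searches can probe exp overflow
        return 1e12
    nll = negative_log_likelihood(model, native, sub)
    if not np.isfinite(nll):
        return 1e12
    return nll + 0.5 * np.sum((x - m) ** 2 / v)


def _numeric_hessian(f, x, h=1e-3):
    d = x.shape[0]
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h
            fab = f(x + ei + ej); fa = f(x + ei - ej)
            fb = f(x - ei + ej); fba = f(x - ei - ej)
            H[i, j] = H[j, i] = (fab - fa - fb + fba) / (4 * h ** 2)
    return H


def laplace_subject_fit(model_spec: ModelSpec, subject_trials,
                        group_prior=None, rng=None, n_restarts: int = 10,
                        warm_starts: Sequence[np.ndarray] = (),
                        config: FitConfig | None = None) -> SubjectModelFit:
    """MAP fit of one model to one subject under a Gaussian group prior, with
    multi-start optimization and a Laplace log-evidence.

    ``group_prior`` is a ``(mean, var)`` pair of per-parameter arrays in
    unconstrained space (defaults to the config's initial prior).
    """
    cfg = config or FitConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sub = subject_trials if isinstance(subject_trials, SubjectArrays) \
        else prepare_subject_arrays(subject_trials)
    d = model_spec.n_params
    if group_prior is None:
        m = np.full(d, cfg.prior_mean)
        v = np.full(d, cfg.prior_var)
    else:
        m = np.asarray(group_prior[0], float)
        v = np.asarray(group_prior[1], float)

    def objective(x):
        return _neg_log_posterior(x, model_spec, sub, m, v)

    starts = [np.asarray(w, float) for w in warm_starts]
    starts += [m + np.sqrt(v) * rng.standard_normal(d) for _ in range(n_restarts)]
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-10})
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok:
        log.warning("optimizer did not report convergence for %s", model_spec.name)

    x_map = best.x
    obj_min = float(best.fun)
    H = _numeric_hessian(objective, x_map)
    sign, logdet = np.linalg.slogdet(H)
    ridge = cfg.hessian_ridge
    while sign <= 0 and ridge < 1e3:
        log.warning("singular Hessian for %s; adding ridge %g", model_spec.name, ridge)
        sign, logdet = np.linalg.slogdet(H + ridge * np.eye(d))
        ridge *= 10
    try:
        post_var = np.clip(np.diag(np.linalg.inv(H + cfg.hessian_ridge * np.eye(d))),
                           1e-8, None)
    except np.linalg.LinAlgError:
        post_var = np.full(d, cfg.prior_var)
    # log posterior (normalized prior) at MAP + Gaussian integral correction
    log_prior_norm = -0.5 * np.sum(np.log(2 * np.pi * v))
    log_post_map = -obj_min + log_prior_norm
    log_evidence = log_post_map + 0.5 * d * LOG_2PI - 0.5 * logdet
    nll_map = obj_min - 0.5 * np.sum((x_map - m) ** 2 / v)
    return SubjectModelFit(theta=x_map, log_likelihood=-nll_map,
                           log_evidence=float(log_evidence),
                           posterior_var=post_var, converged=bool(any_ok))


# ---------------------------------------------------------------------------
# group-level EM
# ---------------------------------------------------------------------------

def _split_subjects(cohort) -> Dict[str, pd.DataFrame]:
    trials = cohort.trials if hasattr(cohort, "trials") else cohort
    if isinstance(trials, dict):
        return trials
    return {sid: df for sid, df in trials.groupby("subject_id", sort=True)}


def hbi_fit(model_specs: Sequence[ModelSpec], cohort,
            config: FitConfig | None = None) -> GroupFit:
    """Concurrent hierarchical fitting and random-effects comparison of models.

    ``cohort`` may be a trial-table DataFrame (grouped by ``subject_id``), a
    dict of per-subject tables, or a CohortDataset.  Subjects may follow
    different models; responsibilities, frequencies, EP, BOR and PXP are
    estimated from the per-subject Laplace evidences.
    """
    cfg = config or FitConfig()
    models = list(model_specs)
    if not models:
        raise ValueError("need at least one model")
    subjects = _split_subjects(cohort)
    if not subjects:
        raise ValueError("empty cohort")
    subject_ids = list(subjects)
    subs = {sid: prepare_subject_arrays(df) for sid, df in subjects.items()}
    n, K = len(subject_ids), len(models)
    rng = np.random.default_rng(cfg.seed)

    means = {m.name: np.full(m.n_params, cfg.prior_mean) for m in models}
    variances = {m.name: np.full(m.n_params, cfg.prior_var) for m in models}
    freq = np.full(K, 1.0 / K)
    alpha = np.full(K, cfg.dirichlet_prior) + n / K
    fits: Dict[str, Dict[str, SubjectModelFit]] = {sid: {} for sid in subject_ids}
    resp = np.full((n, K), 1.0 / K)
    trace: List[dict] = []

    for iteration in range(cfg.max_iter):
        first = iteration == 0
        evid = np.empty((n, K))
        for j, model in enumerate(models):
            prior = (means[model.name], variances[model.name])
            for i, sid in enumerate(subject_ids):
                warm = [] if first else [fits[sid][model.name].theta]
                fit = laplace_subject_fit(
                    model, subs[sid], group_prior=prior, rng=rng,
                    n_restarts=cfg.n_restarts if first else cfg.warm_restarts,
                    warm_starts=warm, config=cfg)
                fits[sid][model.name] = fit
                evid[i, j] = fit.log_evidence
        log_r = np.log(freq)[None, :] + evid
        log_r -= logsumexp(log_r, axis=1, keepdims=True)
        resp = np.exp(log_r)

        new_alpha = cfg.dirichlet_prior + resp.sum(axis=0)
        new_freq = new_alpha / new_alpha.sum()
        delta = float(np.max(np.abs(new_freq - freq)))
        for j, model in enumerate(models):
            w = resp[:, j]
            tot = w.sum()
            if tot < 1e-6:
                continue
            thetas = np.stack([fits[sid][model.name].theta for sid in subject_ids])
            pvars = np.stack([fits[sid][model.name].posterior_var for sid in subject_ids])
            mean = (w[:, None] * thetas).sum(0) / tot
            var = (w[:, None] * ((thetas - mean) ** 2 + pvars)).sum(0) / tot
            delta = max(delta, float(np.max(np.abs(mean - means[model.name]))))
            means[model.name] = mean
            variances[model.name] = np.maximum(var, cfg.var_floor)
        alpha, freq = new_alpha, new_freq
        trace.append({"iteration": iteration, "frequencies": freq.copy(),
                      "max_change": delta})
        log.info("hbi iteration %d: max change %.2e", iteration, delta)
        if delta < cfg.tol:
            break

    ep = exceedance_probabilities(alpha, cfg.mc_samples,
                                  np.random.default_rng(cfg.seed + 1))
    bor = bayes_omnibus_risk(evid, resp, alpha, cfg.dirichlet_prior)
    pxp = protected_exceedance_probability(ep, bor)
    resp_df = pd.DataFrame(resp, index=subject_ids, columns=[m.name for m in models])
    return GroupFit(models=models, subject_ids=subject_ids, fits=fits,
                    responsibilities=resp_df, group_mean=means, group_var=variances,
                    dirichlet_alpha=alpha, frequencies=freq, exceedance=ep,
                    bor=float(bor), pxp=pxp, trace=trace)


# ---------------------------------------------------------------------------
# model comparison statistics
# ---------------------------------------------------------------------------

def exceedance_probabilities(dirichlet_concentration, n_samples: int = 100_000,
                             rng=None) -> np.ndarray:
    """EP_k: fraction of Dirichlet frequency draws in which model k is the most
    frequent (ties split uniformly)."""
    alpha = np.asarray(dirichlet_concentration, float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentration entries must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = rng.dirichlet(alpha, size=int(n_samples))
    is_max = draws == draws.max(axis=1, keepdims=True)
    weights = is_max / is_max.sum(axis=1, keepdims=True)
    return weights.mean(axis=0)


def protected_exceedance_probability(ep, bor: float) -> np.ndarray:
    """Shrink EP toward uniform by the Bayes omnibus risk."""
    ep = np.asarray(ep, float)
    if not 0.0 <= bor <= 1.0:
        raise ValueError("BOR must lie in [0, 1]")
    return ep * (1.0 - bor) + bor / ep.shape[0]


def bayes_omnibus_risk(log_evidence: np.ndarray, resp: np.ndarray,
                       alpha: np.ndarray, alpha0: float = 1.0) -> float:
    """Posterior probability that model frequencies are uniform (the null),
    from the variational free energy of the free-frequency model (F1) against
    the exact evidence of the uniform-frequency null (F0)."""
    n, K = log_evidence.shape
    # per-subject normalization cancels between F0 and F1
    ref = log_evidence.max(axis=1, keepdims=True)
    e = log_evidence - ref
    f0 = float(np.sum(logsumexp(e, axis=1) - np.log(K)))
    elog_r = digamma(alpha) - digamma(alpha.sum())
    a0 = np.full(K, alpha0)
    kl = (gammaln(alpha.sum()) - gammaln(alpha).sum()
          - gammaln(a0.sum()) + gammaln(a0).sum()
          + np.sum((alpha - a0) * elog_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(resp > 0, resp * np.log(resp), 0.0))
    f1 = float(np.sum(resp * e) + np.sum(resp * elog_r[None, :]) + entropy - kl)
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def model_frequencies(subject_fits) -> pd.DataFrame:
    """Mean responsibility per model plus best-model counts (argmax per
    subject, ties split equally)."""
    resp = subject_fits.responsibilities if isinstance(subject_fits, GroupFit) \
        else pd.DataFrame(subject_fits)
    r = resp.to_numpy(float)
    is_max = r == r.max(axis=1, keepdims=True)
    counts = (is_max / is_max.sum(axis=1, keepdims=True)).sum(axis=0)
    return pd.DataFrame({"model": list(resp.columns),
                         "frequency": r.mean(axis=0),
                         "best_count": counts})
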