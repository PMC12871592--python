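"""Hierarchical Bayesian estimation of per-subject Q-learning parameters.

Each subject's intercept and inverse temperature ``beta_s = (beta0, beta1)``
is drawn from a multivariate normal with group mean ``mu_beta`` and
covariance ``Sigma_beta = diag(tau_beta) @ Omega_beta @ diag(tau_beta)``;
learning rates are pooled through ``alpha_s ~ Beta(a1, a2)``.  Hyperpriors:

    mu_beta  ~ Normal(0, 5)          (5 is the standard deviation)
    tau_beta ~ HalfCauchy(0, 2.5)
    Omega    ~ LKJCorr(2)
    a1, a2   ~ HalfNormal(0, 5)      (positive support for Beta shapes)

The likelihood is the Bernoulli choice model of :mod:`rlbold.rl`.  Groups
(acquisition-only vs. reversal) are fit independently so that the extra
volatility experienced by reversal animals cannot inflate the learning
rates of the acquisition-only group.

The joint posterior is sampled with an adaptive Metropolis-within-Gibbs
scheme on unconstrained coordinates (logit alpha, log tau, atanh rho,
log a): each subject's three parameters are proposed jointly, the seven
group-level parameters singly, with proposal scales adapted during warmup
only.  The default bookkeeping is 4 chains x 2000 iterations with the
first 1000 discarded, i.e. 4000 retained draws per parameter; convergence
is checked with the rank-normalized split Gelman-Rubin statistic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .rl import SubjectParams, TrialLikelihoodInput, _loglik_only, forward_pass

_LOG_2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    chains: int = 4
    iterations: int = 2000  # total per chain, including warmup
    warmup: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    min_acceptance: float = 0.05  # below this, a chain is flagged in metadata

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup


@dataclass
class GroupHyperparams:
    mu_beta: np.ndarray
    tau_beta: np.ndarray
    omega_beta: np.ndarray
    a1: float
    a2: float

    def __post_init__(self) -> None:
        self.mu_beta = np.asarray(self.mu_beta, dtype=float)
        self.tau_beta = np.asarray(self.tau_beta, dtype=float)
        self.omega_beta = np.asarray(self.omega_beta, dtype=float)
        if self.tau_beta.shape != (2,) or np.any(self.tau_beta <= 0):
            raise ValueError("tau_beta must be two positive scales")
        if self.omega_beta.shape != (2, 2) or not np.allclose(
            np.diag(self.omega_beta), 1.0
        ):
            raise ValueError("omega_beta must be a 2x2 correlation matrix")
        if abs(self.omega_beta[0, 1]) >= 1.0:
            raise ValueError("omega_beta must be positive definite")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("a1, a2 must be positive")

    @property
    def sigma_beta(self) -> np.ndarray:
        d = np.diag(self.tau_beta)
        return d @ self.omega_beta @ d


@dataclass
class PosteriorFit:
    draws: Dict[str, np.ndarray]  # name -> (chains, kept)
    rhat: Dict[str, float]
    subject_point_estimates: pd.DataFrame  # subject, alpha, beta0, beta1
    metadata: Dict

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return int(first.size)

    def subject_params(self, subject) -> SubjectParams:
        row = self.subject_point_estimates.set_index("subject").loc[subject]
        return SubjectParams(
            alpha=float(row["alpha"]),
            beta0=float(row["beta0"]),
            beta1=float(row["beta1"]),
        )


def split_groups(phase_labels: Dict) -> Tuple[list, list]:
    """Partition subjects into acquisition-only and reversal groups.

    ``phase_labels`` maps subject id to ``"acquisition"`` or ``"reversal"``
    (the latter meaning the subject underwent the rule reversal).  Each
    group must be non-empty because they are fit independently.
    """
    acq, rev = [], []
    for subject, label in phase_labels.items():
        if label == "acquisition":
            acq.append(subject)
        elif label == "reversal":
            rev.append(subject)
        else:
            raise ValueError(
                f"subject {subject!r} has unknown phase label {label!r}"
            )
    if not acq or not rev:
        raise ValueError(
            "both groups must be non-empty "
            f"(acquisition={len(acq)}, reversal={len(rev)})"
        )
    return acq, rev


# ---------------------------------------------------------------------------
# log-density pieces on unconstrained coordinates
# ---------------------------------------------------------------------------

def _group_constrain(g: np.ndarray):
    """(mu0, mu1, log_tau0, log_tau1, atanh_rho, log_a1, log_a2) -> natural."""
    mu = g[0:2]
    tau = np.exp(g[2:4])
    rho = np.tanh(g[4])
    a1, a2 = np.exp(g[5]), np.exp(g[6])
    return mu, tau, rho, a1, a2


def _group_logprior(g: np.ndarray) -> float:
    mu, tau, rho, a1, a2 = _group_constrain(g)
    lp = -0.5 * np.sum(mu**2) / 25.0  # Normal(0, 5) means
    # HalfCauchy(2.5) scales, with log-Jacobian of tau = exp(g)
    lp += np.sum(-np.log1p((tau / 2.5) ** 2) + np.log(tau))
    # LKJCorr(2) on the 2x2 correlation: density prop. to (1 - rho^2);
    # rho = tanh(z) contributes another log(1 - rho^2)
    lp += 2.0 * np.log1p(-(rho**2))
    # HalfNormal(5) Beta shapes, with log-Jacobian of a = exp(g)
    lp += -(a1**2 + a2**2) / 50.0 + np.log(a1) + np.log(a2)
    return float(lp)


def _subject_logprior(z_alpha, beta0, beta1, g) -> float:
    """Prior of one subject's parameters given the group level.

    Vectorized: scalar inputs give a scalar, array inputs an array sum.
    """
    mu, tau, rho, a1, a2 = _group_constrain(g)
    alpha = expit(z_alpha)
    # Beta(a1, a2) on alpha plus the logit Jacobian alpha*(1-alpha)
    lp = (
        a1 * np.log(alpha)
        + a2 * np.log1p(-alpha)
        - betaln(a1, a2)
    )
    z0 = (beta0 - mu[0]) / tau[0]
    z1 = (beta1 - mu[1]) / tau[1]
    one_m = 1.0 - rho**2
    lp += (
        -0.5 * (z0**2 - 2.0 * rho * z0 * z1 + z1**2) / one_m
        - _LOG_2PI
        - np.log(tau[0] * tau[1])
        - 0.5 * np.log(one_m)
    )
    return float(np.sum(lp))


def _subject_logprior_vec(z_alpha: np.ndarray, betas: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Per-subject prior terms for all subjects at once (group updates)."""
    mu, tau, rho, a1, a2 = _group_constrain(g)
    alpha = expit(z_alpha)
    lp = a1 * np.log(alpha) + a2 * np.log1p(-alpha) - betaln(a1, a2)
    z0 = (betas[:, 0] - mu[0]) / tau[0]
    z1 = (betas[:, 1] - mu[1]) / tau[1]
    one_m = 1.0 - rho**2
    lp += (
        -0.5 * (z0**2 - 2.0 * rho * z0 * z1 + z1**2) / one_m
        - _LOG_2PI
        - np.log(tau[0] * tau[1])
        - 0.5 * np.log(one_m)
    )
    return lp


def sample_prior(rng: np.random.Generator, n_subjects: int = 6):
    """Draw one prior-predictive set of group and subject parameters."""
    mu = rng.normal(0.0, 5.0, size=2)
    tau = np.abs(2.5 * np.tan(np.pi * (rng.random(2) - 0.5)))  # HalfCauchy(2.5)
    rho = 2.0 * rng.beta(2.0, 2.0) - 1.0  # LKJ(2) marginal on a 2x2 matrix
    a1, a2 = np.abs(rng.normal(0.0, 5.0, size=2))
    a1, a2 = max(a1, 1e-6), max(a2, 1e-6)
    omega = np.array([[1.0, rho], [rho, 1.0]])
    hyper = GroupHyperparams(mu, tau, omega, a1, a2)
    betas = rng.multivariate_normal(mu, hyper.sigma_beta, size=n_subjects)
    # extreme shape draws can saturate to 0.0/1.0 in floating point; keep the
    # draws inside the open interval the Beta distribution is defined on
    alphas = np.clip(rng.beta(a1, a2, size=n_subjects), 1e-15, 1.0 - 1e-15)
    return hyper, alphas, betas


# ---------------------------------------------------------------------------
# initialization: coarse per-subject maximum likelihood
# ---------------------------------------------------------------------------

_INIT_ALPHAS = np.array([0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9])
_INIT_BETA0 = np.array([-2.0, -1.0, 0.0, 1.0])
_INIT_BETA1 = np.array([0.0, 1.0, 2.0, 5.0, 8.0, 12.0])


def _coarse_mle(inp: TrialLikelihoodInput) -> Tuple[float, float, float]:
    best, best_ll = (0.3, 0.0, 1.0), -np.inf
    for a in _INIT_ALPHAS:
        dv, _ = forward_pass(inp, a)
        for b0 in _INIT_BETA0:
            for b1 in _INIT_BETA1:
                theta = np.clip(expit(b0 + b1 * dv), 1e-12, 1 - 1e-12)
                ll = float(
                    np.sum(
                        inp.choice * np.log(theta)
                        + (1 - inp.choice) * np.log1p(-theta)
                    )
                )
                if ll > best_ll:
                    best, best_ll = (a, b0, b1), ll
    return best


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def fit_hierarchical(
    data: Sequence[TrialLikelihoodInput],
    config: Optional[SamplerConfig] = None,
    *,
    subject_ids: Optional[Sequence] = None,
    group_label: str = "acquisition",
) -> PosteriorFit:
    """Sample the hierarchical posterior for one group of subjects."""
    config = config or SamplerConfig()
    n_sub = len(data)
    if n_sub < 2:
        raise ValueError("need at least two subjects for a hierarchical fit")
    for s, inp in enumerate(data):
        if len(inp) < 1:
            raise ValueError(f"subject {s} has no trials")
    subject_ids = list(subject_ids) if subject_ids is not None else list(range(n_sub))

    t0 = time.time()
    mle = [_coarse_mle(inp) for inp in data]
    mle_a = np.array([m[0] for m in mle])
    mle_b = np.array([[m[1], m[2]] for m in mle])

    dim_g = 7
    n_kept = config.kept
    all_chains = np.empty((config.chains, n_kept, 3 * n_sub + dim_g))
    accept_rates = []

    for chain in range(config.chains):
        rng = np.random.default_rng((config.seed + 1) * 10_000 + chain)
        # jittered initialization around the coarse MLE
        z_alpha = logit(np.clip(mle_a, 0.01, 0.99)) + 0.3 * rng.standard_normal(n_sub)
        betas = mle_b + 0.3 * rng.standard_normal((n_sub, 2))
        g = np.zeros(dim_g)
        g[0:2] = betas.mean(axis=0)
        g[2:4] = np.log(betas.std(axis=0) + 0.5)
        g[4] = 0.0
        g[5:7] = 0.5  # a1 = a2 = exp(0.5), mild pooling to start

        sub_ll = np.array(
            [
                _loglik_only(
                    inp.odor, inp.choice, inp.reward,
                    float(expit(z_alpha[s])), betas[s, 0], betas[s, 1],
                )
                for s, inp in enumerate(data)
            ]
        )
        if not np.all(np.isfinite(sub_ll)):
            bad = int(np.argmax(~np.isfinite(sub_ll)))
            raise FitError(
                f"non-finite likelihood at initialization for subject {bad} "
                f"(alpha={expit(z_alpha[bad]):.3f}, beta={betas[bad]})"
            )
        sub_lp = np.array(
            [
                _subject_logprior(z_alpha[s], betas[s, 0], betas[s, 1], g)
                for s in range(n_sub)
            ]
        )

        sub_scale = np.full((n_sub, 3), 0.1)
        g_scale = np.full(dim_g, 0.2)
        sub_acc = np.zeros(n_sub)
        g_acc = np.zeros(dim_g)
        batch_sub = np.zeros(n_sub)
        batch_g = np.zeros(dim_g)
        batch_n = 0
        n_batches = 0

        kept_i = 0
        for it in range(config.iterations):
            # --- subject blocks: joint 3-dim proposals ------------------
            eps = rng.standard_normal((n_sub, 3)) * sub_scale
            log_u = np.log(rng.random(n_sub))
            for s in range(n_sub):
                za_new = z_alpha[s] + eps[s, 0]
                b0_new = betas[s, 0] + eps[s, 1]
                b1_new = betas[s, 1] + eps[s, 2]
                lp_new = _subject_logprior(za_new, b0_new, b1_new, g)
                inp = data[s]
                ll_new = _loglik_only(
                    inp.odor, inp.choice, inp.reward,
                    float(expit(za_new)), b0_new, b1_new,
                )
                if log_u[s] < (lp_new + ll_new) - (sub_lp[s] + sub_ll[s]):
                    z_alpha[s], betas[s, 0], betas[s, 1] = za_new, b0_new, b1_new
                    sub_lp[s], sub_ll[s] = lp_new, ll_new
                    sub_acc[s] += 1
                    batch_sub[s] += 1
            # --- group parameters: scalar proposals ---------------------
            g_lp = _group_logprior(g)
            g_eps = rng.standard_normal(dim_g) * g_scale
            g_log_u = np.log(rng.random(dim_g))
            for j in range(dim_g):
                g_new = g.copy()
                g_new[j] += g_eps[j]
                lp_new_g = _group_logprior(g_new)
                sub_lp_new = _subject_logprior_vec(z_alpha, betas, g_new)
                if g_log_u[j] < (lp_new_g + sub_lp_new.sum()) - (g_lp + sub_lp.sum()):
                    g, g_lp, sub_lp = g_new, lp_new_g, sub_lp_new
                    g_acc[j] += 1
                    batch_g[j] += 1
            batch_n += 1
            # --- warmup-only proposal adaptation ------------------------
            if it < config.warmup and batch_n == 50:
                n_batches += 1
                delta = min(0.1, 1.0 / np.sqrt(n_batches))
                rate_s = batch_sub / batch_n
                sub_scale *= np.exp(
                    np.where(rate_s > 0.25, delta, -delta)
                )[:, None]
                rate_g = batch_g / batch_n
                g_scale *= np.exp(np.where(rate_g > 0.44, delta, -delta))
                batch_sub[:] = 0.0
                batch_g[:] = 0.0
                batch_n = 0
            if it >= config.warmup:
                all_chains[chain, kept_i, : 3 * n_sub : 3] = expit(z_alpha)
                all_chains[chain, kept_i, 1 : 3 * n_sub : 3] = betas[:, 0]
                all_chains[chain, kept_i, 2 : 3 * n_sub : 3] = betas[:, 1]
                mu, tau, rho, a1, a2 = _group_constrain(g)
                all_chains[chain, kept_i, 3 * n_sub :] = [
                    mu[0], mu[1], tau[0], tau[1], rho, a1, a2,
                ]
                kept_i += 1
        accept_rates.append(
            {
                "subject_blocks": float(np.mean(sub_acc) / config.iterations),
                "group_scalars": float(np.mean(g_acc) / config.iterations),
            }
        )

    names: List[str] = []
    for s in range(n_sub):
        names += [f"alpha[{s}]", f"beta0[{s}]", f"beta1[{s}]"]
    names += [
        "mu_beta[0]", "mu_beta[1]",
        "tau_beta[0]", "tau_beta[1]",
        "omega_beta[0,1]", "a1", "a2",
    ]
    draws = {name: all_chains[:, :, j].copy() for j, name in enumerate(names)}

    rhat = _rhat_dict(draws) if config.chains >= 2 else {}
    warnings = [
        f"rhat above {config.rhat_threshold}: {name} = {val:.3f}"
        for name, val in rhat.items()
        if val > config.rhat_threshold
    ]
    for c, rates in enumerate(accept_rates):
        if rates["subject_blocks"] < config.min_acceptance:
            warnings.append(
                f"chain {c} subject-block acceptance "
                f"{rates['subject_blocks']:.3f} below {config.min_acceptance}"
            )

    est = pd.DataFrame(
        {
            "subject": subject_ids,
            "alpha": [draws[f"alpha[{s}]"].mean() for s in range(n_sub)],
            "beta0": [draws[f"beta0[{s}]"].mean() for s in range(n_sub)],
            "beta1": [draws[f"beta1[{s}]"].mean() for s in range(n_sub)],
        }
    )
    meta = {
        "seed": config.seed,
        "group": group_label,
        "n_subjects": n_sub,
        "n_trials": [len(inp) for inp in data],
        "chains": config.chains,
        "iterations": config.iterations,
        "warmup": config.warmup,
        "kept_per_chain": n_kept,
        "acceptance": accept_rates,
        "warnings": warnings,
        "wall_time_s": time.time() - t0,
    }
    return PosteriorFit(
        draws=draws, rhat=rhat, subject_point_estimates=est, metadata=meta
    )


def _rhat_dict(draws: Dict[str, np.ndarray]) -> Dict[str, float]:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in draws.items()})
    rh = az.rhat(ds)
    return {k: float(rh[k].values) for k in draws}


def check_convergence(fit: PosteriorFit, threshold: float = 1.05) -> Dict:
    """Rank-normalized split Gelman-Rubin check for every sampled quantity."""
    some = next(iter(fit.draws.values()))
    if some.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    rhat = _rhat_dict(fit.draws)
    failures = {k: v for k, v in rhat.items() if v > threshold}
    return {
        "rhat": rhat,
        "threshold": threshold,
        "passed": not failures,
        "failures": failures,
    }


def decision_variable_series(
    fit: PosteriorFit, subject, inp: TrialLikelihoodInput
) -> np.ndarray:
    """Per-trial decision variable at the subject's posterior-mean parameters.

    The forward pass runs over the subject's realized choices and rewards,
    i.e. the same recursion the likelihood uses, so it matches
    :func:`rlbold.rl.sequence_loglik` exactly at equal parameters.
    """
    params = fit.subject_params(subject)
    dv, _ = forward_pass(inp, params.alpha)
    return dv
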