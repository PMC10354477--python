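"""Bayesian Bernoulli regression with a phylogenetic group-level effect.

Model, for species i with binary response y and predictor x:

    logit P(y_i = 1) = b0 + b1 * x_i + u_i,      u ~ MVN(0, sigma^2 * C)

where C is the shared root-path branch-length covariance of the tree,
scaled to unit diagonal so sigma^2 is the phylogenetic variance on the
logit scale.  Inference is Metropolis-within-Gibbs on (b0, b1), the
non-centred latent z (u = sigma * L z, C = L L'), and log sigma, with
proposal scales adapted during warm-up.  The predictor is standardized
internally and draws are mapped back, making the reported slope exactly
affine-equivariant in x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .tree import PhyloTree

__all__ = ["GlmPriors", "PhyloGlmResult", "phylo_covariance", "fit_phyloglm"]


@dataclass(frozen=True)
class GlmPriors:
    """Normal(0, beta_sd^2) on coefficients, half-normal(0, sigma_sd) on sigma."""

    beta_sd: float = 10.0
    sigma_sd: float = 5.0


@dataclass(frozen=True)
class PhyloGlmResult:
    draws: dict  # name -> array (chains, draws)
    ci95: dict  # name -> (low, high)
    posterior_mean: dict
    rhat: dict
    converged: bool
    accept_rates: dict

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)


def phylo_covariance(tree: PhyloTree, tip_order: Sequence[str]) -> np.ndarray:
    """Shared root-path length between tips, scaled to unit diagonal."""
    tips = {t.label: t for t in tree.tips()}
    missing = [lbl for lbl in tip_order if lbl not in tips]
    if missing:
        raise ValueError(f"tips not in tree: {missing}")

    def path(node):
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return out

    paths = {lbl: path(tips[lbl]) for lbl in tip_order}
    node_depth: dict[int, float] = {}
    n = len(tip_order)
    C = np.zeros((n, n))
    for a in range(n):
        pa = paths[tip_order[a]]
        set_a = {id(x) for x in pa}
        C[a, a] = sum(x.length for x in pa)
        for b in range(a + 1, n):
            shared = sum(
                x.length for x in paths[tip_order[b]] if id(x) in set_a
            )
            C[a, b] = C[b, a] = shared
    d = np.sqrt(np.diag(C))
    if np.any(d == 0):
        raise ValueError("zero root-to-tip length; cannot scale covariance")
    return C / np.outer(d, d)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an array of shape (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    if half < 2:
        return np.nan
    splits = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def fit_phyloglm(
    tree: Optional[PhyloTree],
    response: Mapping[str, int] | Sequence[int],
    predictor: Mapping[str, float] | Sequence[float],
    priors: GlmPriors = GlmPriors(),
    chains: int = 4,
    draws: int = 5000,
    warmup: int = 2000,
    seed: int = 0,
    sigma_fixed: Optional[float] = None,
    tip_order: Optional[Sequence[str]] = None,
) -> PhyloGlmResult:
    """Fit the phylogenetic Bernoulli regression.

    ``tree=None`` (or ``sigma_fixed=0``) drops the group-level effect,
    reducing to ordinary Bayesian logistic regression.  With a tree,
    ``response`` and ``predictor`` may be mappings keyed by tip label.
    Deterministic given ``seed`` and the sampler settings.
    """
    if isinstance(response, Mapping):
        if tip_order is None:
            tip_order = tree.tip_labels() if tree is not None else sorted(response)
        y = np.asarray([response[k] for k in tip_order], dtype=float)
        x = np.asarray([predictor[k] for k in tip_order], dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("response and predictor lengths differ")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    n = len(y)

    x_mean, x_sd = float(np.mean(x)), float(np.std(x, ddof=0))
    if x_sd == 0:
        raise ValueError("predictor is constant")
    xs = (x - x_mean) / x_sd

    use_latent = not (tree is None or sigma_fixed == 0.0)
    if use_latent:
        if tip_order is None and isinstance(response, Mapping):
            tip_order = list(response)
        if tree is None:
            raise ValueError("a tree is required unless sigma_fixed=0")
        C = phylo_covariance(tree, tip_order) if tip_order is not None else None
        if C is None:
            raise ValueError("tip_order required to align tree with data arrays")
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    else:
        L = None

    rng_master = np.random.default_rng(seed)
    chain_rngs = rng_master.spawn(chains)

    names = ["intercept", "slope", "sigma"]
    all_draws = {name: np.zeros((chains, draws)) for name in names}
    accept_tot = {"beta": 0.0, "z": 0.0, "sigma": 0.0}

    for c in range(chains):
        rng = chain_rngs[c]
        beta = rng.normal(0.0, 0.1, size=2)
        z = np.zeros(n)
        log_sigma = np.log(sigma_fixed) if (use_latent and sigma_fixed) else np.log(0.5)
        sigma = (
            float(sigma_fixed)
            if (use_latent and sigma_fixed is not None)
            else (np.exp(log_sigma) if use_latent else 0.0)
        )
        sample_sigma = use_latent and sigma_fixed is None

        scale_beta, scale_z, scale_sig = 0.3, 0.5, 0.3
        u_vec = sigma * (L @ z) if use_latent else 0.0

        def log_post(beta_, u_) -> float:
            eta = beta_[0] + beta_[1] * xs + u_
            lp = _bernoulli_loglik(y, eta)
            lp += -0.5 * np.sum(beta_**2) / priors.beta_sd**2
            return lp

        n_acc = {"beta": 0, "z": 0, "sigma": 0}
        n_try = {"beta": 0, "z": 0, "sigma": 0}
        lp_cur = log_post(beta, u_vec)

        for it in range(warmup + draws):
            # -- coefficients ------------------------------------------------
            prop = beta + scale_beta * rng.normal(size=2)
            lp_prop = log_post(prop, u_vec)
            n_try["beta"] += 1
            if np.log(rng.random()) < lp_prop - lp_cur:
                beta, lp_cur = prop, lp_prop
                n_acc["beta"] += 1

            # -- latent field (non-centred) ---------------------------------
            if use_latent:
                z_prop = z + scale_z * rng.normal(size=n)
                u_prop = sigma * (L @ z_prop)
                lp_prop = log_post(beta, u_prop) - 0.5 * np.sum(z_prop**2)
                lp_z_cur = lp_cur - 0.5 * np.sum(z**2)
                n_try["z"] += 1
                if np.log(rng.random()) < lp_prop - lp_z_cur:
                    z, u_vec = z_prop, u_prop
                    lp_cur = log_post(beta, u_vec)
                    n_acc["z"] += 1

            # -- sigma -------------------------------------------------------
            if sample_sigma:
                ls_prop = log_sigma + scale_sig * rng.normal()
                sig_prop = np.exp(ls_prop)
                u_prop = sig_prop * (L @ z)
                # half-normal prior + log-scale Jacobian
                lp_prop = (
                    log_post(beta, u_prop)
                    - 0.5 * sig_prop**2 / priors.sigma_sd**2
                    + ls_prop
                )
                lp_sig_cur = (
                    lp_cur - 0.5 * sigma**2 / priors.sigma_sd**2 + log_sigma
                )
                n_try["sigma"] += 1
                if np.log(rng.random()) < lp_prop - lp_sig_cur:
                    log_sigma, sigma, u_vec = ls_prop, sig_prop, u_prop
                    lp_cur = log_post(beta, u_vec)
                    n_acc["sigma"] += 1

            # -- warm-up adaptation -----------------------------------------
            if it < warmup and (it + 1) % 50 == 0:
                for key, scale_name in (("beta", "beta"), ("z", "z"), ("sigma", "sigma")):
                    if n_try[key] == 0:
                        continue
                    rate = n_acc[key] / n_try[key]
                    factor = np.exp(0.5 * (rate - 0.3))
                    if key == "beta":
                        scale_beta = float(np.clip(scale_beta * factor, 1e-3, 10))
                    elif key == "z":
                        scale_z = float(np.clip(scale_z * factor, 1e-3, 10))
                    else:
                        scale_sig = float(np.clip(scale_sig * factor, 1e-3, 10))
                    n_acc[key] = n_try[key] = 0

            if it >= warmup:
                k = it - warmup
                # map standardized-scale draws back to the raw predictor scale
                all_draws["slope"][c, k] = beta[1] / x_sd
                all_draws["intercept"][c, k] = beta[0] - beta[1] * x_mean / x_sd
                all_draws["sigma"][c, k] = sigma

        for key in accept_tot:
            if n_try[key]:
                accept_tot[key] += n_acc[key] / n_try[key] / chains

    ci95, post_mean, rhat = {}, {}, {}
    for name in names:
        pooled = all_draws[name].reshape(-1)
        ci95[name] = (float(np.percentile(pooled, 2.5)),
                      float(np.percentile(pooled, 97.5)))
        post_mean[name] = float(np.mean(pooled))
        rhat[name] = _split_rhat(all_draws[name])

    active = ["intercept", "slope"] + (["sigma"] if use_latent and sigma_fixed is None else [])
    converged = all(
        np.isnan(rhat[name]) or rhat[name] < 1.05 for name in active
    )
    if not converged:
        import warnings

        warnings.warn(
            "MCMC convergence diagnostics exceed 1.05: "
            + ", ".join(f"{k}={rhat[k]:.3f}" for k in active),
            RuntimeWarning,
            stacklevel=2,
        )
    return PhyloGlmResult(
        draws=all_draws,
        ci95=ci95,
        posterior_mean=post_mean,
        rhat=rhat,
        converged=converged,
        accept_rates=accept_tot,
    )
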