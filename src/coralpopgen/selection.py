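"""Hierarchical F-model scan for loci under divergent selection.

The logistic F-model decomposes locus-by-population differentiation into
a locus-specific (selection) effect alpha_l and a population-specific
(drift) effect beta_p:

    FST_{l,p} = 1 / (1 + exp(-(alpha_l + beta_p)))

Population allele frequencies follow the Balding-Nichols distribution
Beta(theta * pbar_l, theta * (1 - pbar_l)) with theta = (1-FST)/FST =
exp(-(alpha_l + beta_p)) around the ancestral frequency pbar_l, and
observed ALT allele counts are binomial given the population frequency.
A spike-and-slab prior on alpha_l (point mass at zero versus a diffuse
normal slab) makes the posterior inclusion probability of a nonzero
locus effect directly available from the Metropolis-within-Gibbs chain;
divergent selection is alpha_l > 0 (excess differentiation).

Selection calls use the posterior-based FDR rule: rank loci by
P(divergent) and flag the largest prefix whose mean posterior
probability of neutrality stays at or below the target FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit
from sklearn.base import BaseEstimator

from .variants import GenotypeMatrix

__all__ = [
    "McmcSettings",
    "FModelResult",
    "SelectionCall",
    "FModelScan",
    "fit_fmodel",
    "call_selection",
    "allele_counts_by_population",
    "scan_genome",
]


@dataclass(frozen=True)
class McmcSettings:
    """Chain settings.  Defaults are sized for desk runs; production-scale
    scans simply raise the iteration counts."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    prior_inclusion: float = 0.1
    slab_sd: float = 2.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if not 0 < self.prior_inclusion < 1:
            raise ValueError("prior_inclusion must be in (0, 1)")


@dataclass
class FModelResult:
    posterior_divergent: np.ndarray  # P(delta=1 and alpha>0) per locus
    posterior_inclusion: np.ndarray  # P(delta=1) per locus
    alpha_mean: np.ndarray
    beta_mean: np.ndarray
    beta_rhat: np.ndarray
    n_draws: int
    settings: McmcSettings
    skipped_monomorphic: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    converged: bool = True


@dataclass
class SelectionCall:
    flagged: np.ndarray  # boolean per locus
    posterior: np.ndarray
    fdr_target: float
    realized_fdr: float
    fraction_flagged: float


def allele_counts_by_population(
    gm: GenotypeMatrix, populations
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-locus, per-population ALT counts and allele totals.

    Returns ``(alt, total, labels)`` with shapes (n_sites, n_pops).
    """
    populations = pd.Series(populations)
    labels = sorted(set(populations.loc[populations.index.intersection(gm.sample_ids)]))
    alt = np.zeros((gm.n_sites, len(labels)), dtype=np.int64)
    tot = np.zeros_like(alt)
    for j, lab in enumerate(labels):
        members = [i for i, s in enumerate(gm.sample_ids) if populations.get(s) == lab]
        d = gm.dosages[members, :]
        typed = d >= 0
        alt[:, j] = np.where(typed, d, 0).sum(axis=0)
        tot[:, j] = 2 * typed.sum(axis=0)
    return alt, tot, labels


def _log_beta_pdf(p, theta, pbar):
    a = theta * pbar
    b = theta * (1.0 - pbar)
    return (a - 1.0) * np.log(p) + (b - 1.0) * np.log1p(-p) - betaln(a, b)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat from a single chain (split into halves)."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


class FModelScan(BaseEstimator):
    """Estimator interface for the F-model selection scan.

    Attributes (after fit): ``result_`` (:class:`FModelResult`),
    ``posterior_divergent_``, ``beta_mean_``.
    """

    def __init__(
        self,
        n_iter: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 10,
        seed: int = 0,
        prior_inclusion: float = 0.1,
        slab_sd: float = 2.0,
        beta_fixed: np.ndarray | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_inclusion = prior_inclusion
        self.slab_sd = slab_sd
        self.beta_fixed = beta_fixed

    def fit(self, alt: np.ndarray, total: np.ndarray):
        settings = McmcSettings(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            seed=self.seed, prior_inclusion=self.prior_inclusion,
            slab_sd=self.slab_sd,
        )
        self.result_ = fit_fmodel(alt, total, settings, beta_fixed=self.beta_fixed)
        self.posterior_divergent_ = self.result_.posterior_divergent
        self.beta_mean_ = self.result_.beta_mean
        return self


def fit_fmodel(
    alt: np.ndarray,
    total: np.ndarray,
    settings: McmcSettings = McmcSettings(),
    beta_fixed: np.ndarray | None = None,
) -> FModelResult:
    """Metropolis-within-Gibbs sampler for the logistic F-model.

    Parameters
    ----------
    alt, total
        (n_loci, n_pops) ALT allele counts and allele totals.
    settings
        Chain configuration.
    beta_fixed
        When given, population drift parameters are held at these values
        (the second pass of the two-pass contig-wise mode).

    Loci monomorphic across all populations are skipped (reported in
    ``skipped_monomorphic`` with posterior 0).
    """
    alt = np.asarray(alt, dtype=np.float64)
    total = np.asarray(total, dtype=np.float64)
    if alt.shape != total.shape:
        raise ValueError("alt and total shapes differ")
    if np.any(alt > total):
        raise ValueError("ALT counts exceed allele totals")
    L_all, P = alt.shape
    if P < 2:
        raise ValueError("need at least 2 populations")

    mono = (alt.sum(axis=1) == 0) | (alt.sum(axis=1) == total.sum(axis=1))
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic loci skipped")
    keep = ~mono
    alt_k, tot_k = alt[keep], total[keep]
    L = alt_k.shape[0]

    rng = np.random.default_rng(settings.seed)
    eps = 1e-6
    p = np.clip(alt_k / np.maximum(tot_k, 1.0), eps, 1 - eps)
    pbar = np.clip(p.mean(axis=1), eps, 1 - eps)
    beta = (
        np.full(P, settings.beta_prior_mean)
        if beta_fixed is None
        else np.asarray(beta_fixed, dtype=np.float64).copy()
    )
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)

    n_draws = (settings.n_iter - settings.burn_in) // settings.thin
    sum_div = np.zeros(L)
    sum_incl = np.zeros(L)
    sum_alpha = np.zeros(L)
    beta_draws = np.zeros((n_draws, P))
    draw = 0

    step_p, step_pbar, step_alpha, step_beta = 0.8, 0.25, 0.6, 0.15
    logit = lambda u: np.log(u) - np.log1p(-u)

    def theta_of(a, b):
        return np.exp(-np.clip(a[:, None] + b[None, :], -25.0, 25.0))

    theta = theta_of(alpha * delta, beta)
    cur = _log_beta_pdf(p, theta, pbar[:, None])  # cached current log-prior
    for it in range(settings.n_iter):
        # -- population frequencies p_{l,p} (logit random walk) ------------
        prop = expit(logit(p) + rng.normal(0.0, step_p, p.shape))
        prop = np.clip(prop, eps, 1 - eps)
        loglik = (
            alt_k * (np.log(prop) - np.log(p))
            + (tot_k - alt_k) * (np.log1p(-prop) - np.log1p(-p))
        )
        prop_lp = _log_beta_pdf(prop, theta, pbar[:, None])
        # Jacobian of the logit transform: log p(1-p)
        jac = np.log(prop) + np.log1p(-prop) - np.log(p) - np.log1p(-p)
        acc = np.log(rng.random(p.shape)) < loglik + prop_lp - cur + jac
        p = np.where(acc, prop, p)
        cur = np.where(acc, prop_lp, cur)

        # -- ancestral frequencies pbar_l ----------------------------------
        prop = expit(logit(pbar) + rng.normal(0.0, step_pbar, L))
        prop = np.clip(prop, eps, 1 - eps)
        prop_lp = _log_beta_pdf(p, theta, prop[:, None])
        dlp = (
            prop_lp.sum(axis=1) - cur.sum(axis=1)
            + np.log(prop) + np.log1p(-prop) - np.log(pbar) - np.log1p(-pbar)
        )
        accv = np.log(rng.random(L)) < dlp
        pbar = np.where(accv, prop, pbar)
        cur = np.where(accv[:, None], prop_lp, cur)

        # -- locus effects: spike-and-slab alpha_l -------------------------
        toggle = rng.random(L) < 0.5
        prop_alpha = np.where(
            delta, alpha + rng.normal(0.0, step_alpha, L), rng.normal(0.0, settings.slab_sd, L)
        )
        prop_delta = np.where(toggle, ~delta, delta)
        prop_alpha = np.where(toggle & ~delta, rng.normal(0.0, settings.slab_sd, L), prop_alpha)
        eff_new = np.where(prop_delta, prop_alpha, 0.0)
        th_new = theta_of(eff_new, beta)
        prop_lp = _log_beta_pdf(p, th_new, pbar[:, None])
        dll = (prop_lp - cur).sum(axis=1)
        prior_odds = np.log(settings.prior_inclusion) - np.log1p(-settings.prior_inclusion)
        # birth/death: proposal from the slab cancels the slab prior term
        dprior = np.where(
            toggle,
            np.where(prop_delta, prior_odds, -prior_odds),
            # random-walk move within the slab
            np.where(
                delta,
                -0.5 * (prop_alpha**2 - alpha**2) / settings.slab_sd**2,
                0.0,
            ),
        )
        move_happens = toggle | delta  # spike loci without toggle: no move
        acc = (np.log(rng.random(L)) < dll + dprior) & move_happens
        alpha = np.where(acc, np.where(prop_delta, prop_alpha, alpha), alpha)
        delta = np.where(acc, prop_delta, delta)
        theta = np.where(acc[:, None], th_new, theta)
        cur = np.where(acc[:, None], prop_lp, cur)

        # -- population effects beta_p -------------------------------------
        if beta_fixed is None:
            # the likelihood separates by population column, so all beta_p
            # can be proposed and accepted independently in one pass
            bprop = beta + rng.normal(0.0, step_beta, P)
            th_new = theta_of(np.where(delta, alpha, 0.0), bprop)
            prop_lp = _log_beta_pdf(p, th_new, pbar[:, None])
            dll = (prop_lp - cur).sum(axis=0)
            dpr = -0.5 * (
                (bprop - settings.beta_prior_mean) ** 2
                - (beta - settings.beta_prior_mean) ** 2
            ) / settings.beta_prior_sd**2
            accb = np.log(rng.random(P)) < dll + dpr
            beta = np.where(accb, bprop, beta)
            theta = np.where(accb[None, :], th_new, theta)
            cur = np.where(accb[None, :], prop_lp, cur)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            sum_incl += delta
            sum_div += delta & (alpha > 0)
            sum_alpha += np.where(delta, alpha, 0.0)
            beta_draws[draw] = beta
            draw += 1

    rhat = np.array([_split_rhat(beta_draws[:draw, j]) for j in range(P)])
    converged = bool(np.all(np.isnan(rhat) | (rhat <= 1.1)))
    if not converged:
        warnings.warn(f"beta split-R-hat above 1.1: {np.round(rhat, 3)}")

    post_div = np.zeros(L_all)
    post_incl = np.zeros(L_all)
    a_mean = np.zeros(L_all)
    post_div[keep] = sum_div / draw
    post_incl[keep] = sum_incl / draw
    a_mean[keep] = sum_alpha / draw
    return FModelResult(
        posterior_divergent=post_div,
        posterior_inclusion=post_incl,
        alpha_mean=a_mean,
        beta_mean=beta_draws[:draw].mean(axis=0),
        beta_rhat=rhat,
        n_draws=draw,
        settings=settings,
        skipped_monomorphic=np.flatnonzero(mono),
        converged=converged,
    )


def call_selection(posterior: np.ndarray | FModelResult, fdr_target: float = 0.05) -> SelectionCall:
    """Flag the largest posterior-ranked set whose mean neutrality
    probability stays at or below ``fdr_target``."""
    if not 0.0 < fdr_target < 1.0:
        raise ValueError("fdr_target must be in (0, 1)")
    post = (
        posterior.posterior_divergent
        if isinstance(posterior, FModelResult)
        else np.asarray(posterior, dtype=np.float64)
    )
    order = np.argsort(-post, kind="stable")
    neutral = 1.0 - post[order]
    cum_fdr = np.cumsum(neutral) / np.arange(1, len(post) + 1)
    k = int(np.max(np.flatnonzero(cum_fdr <= fdr_target)) + 1) if np.any(cum_fdr <= fdr_target) else 0
    flagged = np.zeros(len(post), dtype=bool)
    flagged[order[:k]] = True
    realized = float(cum_fdr[k - 1]) if k else 0.0
    return SelectionCall(
        flagged=flagged,
        posterior=post,
        fdr_target=fdr_target,
        realized_fdr=realized,
        fraction_flagged=float(flagged.mean()),
    )


def scan_genome(
    gm: GenotypeMatrix,
    populations,
    settings: McmcSettings = McmcSettings(),
    two_pass: bool = True,
    min_loci_full: int = 200,
) -> FModelResult:
    """Contig-wise F-model scan over a genotype matrix.

    Two-pass mode mirrors running one chain per contig with shared
    demographic parameters: pass one estimates the population drift
    effects beta on the largest contig (or all loci when small), and
    pass two fixes beta while fitting the locus effects contig by
    contig.
    """
    alt, tot, labels = allele_counts_by_population(gm, populations)
    if not two_pass or gm.n_sites <= min_loci_full:
        return fit_fmodel(alt, tot, settings)
    contigs = pd.Series(gm.contigs)
    largest = contigs.value_counts().idxmax()
    first = contigs == largest
    res1 = fit_fmodel(alt[first.to_numpy()], tot[first.to_numpy()], settings)
    post = np.zeros(gm.n_sites)
    incl = np.zeros(gm.n_sites)
    amean = np.zeros(gm.n_sites)
    for k, ctg in enumerate(contigs.unique()):
        rows = (contigs == ctg).to_numpy()
        sub_settings = McmcSettings(
            n_iter=settings.n_iter, burn_in=settings.burn_in, thin=settings.thin,
            seed=settings.seed + 1 + k, prior_inclusion=settings.prior_inclusion,
            slab_sd=settings.slab_sd, beta_prior_mean=settings.beta_prior_mean,
            beta_prior_sd=settings.beta_prior_sd,
        )
        sub = fit_fmodel(alt[rows], tot[rows], sub_settings, beta_fixed=res1.beta_mean)
        post[rows] = sub.posterior_divergent
        incl[rows] = sub.posterior_inclusion
        amean[rows] = sub.alpha_mean
    return FModelResult(
        posterior_divergent=post,
        posterior_inclusion=incl,
        alpha_mean=amean,
        beta_mean=res1.beta_mean,
        beta_rhat=res1.beta_rhat,
        n_draws=res1.n_draws,
        settings=settings,
        converged=res1.converged,
    )
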