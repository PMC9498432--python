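"""Bayesian F_st-outlier scan with reversible-jump MCMC and q-values.

The model treats the allele_a2 count of locus ``i`` in cohort ``j`` as
binomial given an unobserved cohort frequency that is integrated out
against a Beta distribution centred on the ancestral frequency ``p_i``
with dispersion set by a locus-and-cohort F_st — the biallelic special
case of the multinomial-Dirichlet migration-drift model used by Bayesian
selection scans:

    n_a2[i,j] | p_i, F_ij  ~  BetaBinomial(n_total[i,j];
                                           theta_ij p_i, theta_ij (1-p_i)),
    theta_ij = 1/F_ij - 1,
    logit(F_ij) = alpha_i * delta_i + beta_j.

``beta_j`` captures the cohort-specific drift shared by all loci;
``alpha_i`` is a locus-specific selection effect that is present only when
the binary indicator ``delta_i`` is on. A reversible-jump move switches
``delta_i`` each sweep, so the posterior frequency of ``delta_i = 1`` is
the posterior probability that locus ``i`` departs from the genome-wide
drift model. q-values convert those probabilities into the minimum false
discovery rate at which each locus would be called significant.

All locus-level updates are vectorised across loci (they are conditionally
independent given the cohort effects), which keeps desk-scale chains
(thousands of loci, a few cohorts) to well under a minute per thousand
sweeps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import betaln, expit, logit

from .diff_stats import AlleleCountTable
from .genotype_io import LocusRecord

logger = logging.getLogger(__name__)

_ALPHA_SD = 3.0  # prior sd of the locus effect (log-odds scale)
_BETA_MEAN, _BETA_SD = -1.0, 1.8  # prior on cohort effects
_F_EPS = 1e-9  # keep F_ij strictly inside (0, 1)


@dataclass
class McmcConfig:
    """Chain-length and prior settings for :func:`fit`.

    ``prior_odds`` is the prior odds of a locus being neutral versus
    selected (10 means 10:1 against inclusion); ``math.inf`` pins every
    ``delta_i`` at 0. Defaults are desk-scale — shorter than the chains a
    production BayeScan-style run would use, but long enough for the
    calibration and recovery behaviour documented in the methods note.
    """

    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 10
    n_pilot: int = 10
    pilot_len: int = 200
    prior_odds: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not self.prior_odds > 0:
            raise ValueError("prior_odds must be positive")


@dataclass
class PosteriorSummary:
    """Per-locus posterior summaries of one chain."""

    loci: list[LocusRecord]
    p_incl: np.ndarray  # posterior P(delta_i = 1)
    q: np.ndarray
    fst_mean: np.ndarray  # posterior mean of F_ij averaged over cohorts
    alpha_mean: np.ndarray
    n_excluded_monomorphic: int = 0
    config: McmcConfig | None = None

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["snp\tchrom\tbp\tp_incl\tq\tfst_post\talpha_post"]
        for i, l in enumerate(self.loci):
            lines.append(
                f"{l.id}\t{l.chrom}\t{l.bp}\t{self.p_incl[i]:.6f}\t{self.q[i]:.6f}"
                f"\t{self.fst_mean[i]:.6f}\t{self.alpha_mean[i]:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _loglik(
    k: np.ndarray, n: np.ndarray, p_anc: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """Beta-binomial log likelihood per (locus, cohort).

    ``eta = alpha*delta + beta`` on the logit scale; the binomial
    coefficient is omitted (constant in every Metropolis ratio).
    """
    f = np.clip(expit(eta), _F_EPS, 1 - _F_EPS)
    theta = 1.0 / f - 1.0
    a = theta * p_anc[:, None]
    b = theta * (1.0 - p_anc[:, None])
    return betaln(k + a, n - k + b) - betaln(a, b)


def q_values(p_incl: np.ndarray) -> np.ndarray:
    """q-value per locus from posterior inclusion probabilities.

    Ranking loci by descending P, the q-value at rank r is the running
    mean of (1 - P) over the top r loci — the expected fraction of false
    positives if the list were cut there — made monotone non-decreasing
    down the ranking and reported in the input order.
    """
    p = np.asarray(p_incl, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-p, kind="stable")
    running = np.cumsum(1.0 - p[order]) / np.arange(1, p.size + 1)
    running = np.maximum.accumulate(running)
    # tied P share one q: the running value at the tie group's last rank
    p_sorted = p[order]
    for start in range(p.size):
        if start == 0 or p_sorted[start] != p_sorted[start - 1]:
            end = start
            while end + 1 < p.size and p_sorted[end + 1] == p_sorted[start]:
                end += 1
            running[start : end + 1] = running[end]
    q = np.empty_like(p)
    q[order] = running
    return q


def significant_loci(summary: PosteriorSummary, q_max: float = 0.05) -> list[str]:
    """Locus ids with q strictly below ``q_max``."""
    if not (0 < q_max < 1):
        raise ValueError("q_max must be in (0, 1)")
    return [l.id for l, q in zip(summary.loci, summary.q) if q < q_max]


class _Chain:
    """Mutable MCMC state over L loci and J cohorts."""

    def __init__(self, counts: AlleleCountTable, cfg: McmcConfig, rng: np.random.Generator):
        self.k = counts.n_a2.T.astype(float)  # (L, J)
        self.n = counts.n_total.T.astype(float)
        self.L, self.J = self.k.shape
        self.cfg = cfg
        self.rng = rng

        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = self.k.sum(axis=1) / np.maximum(self.n.sum(axis=1), 1.0)
        self.p = np.clip(pooled, 0.01, 0.99)
        self.alpha = np.zeros(self.L)
        self.delta = np.zeros(self.L, dtype=bool)
        self.beta = np.full(self.J, _BETA_MEAN)
        self.log_incl_prior = (
            -math.inf if math.isinf(cfg.prior_odds) else -math.log(cfg.prior_odds)
        )

        # proposal scales, pilot-tuned
        self.sd_p = 0.5  # logit scale
        self.sd_alpha = 0.5
        self.sd_beta = 0.2
        self.sd_rj = 1.5  # birth proposal sd for alpha

        # Birth proposals are centred on a fixed per-locus moment estimate
        # of alpha (logit of the locus's naive F_st minus the genome-wide
        # logit), which lets the jump land where the likelihood lives.
        # The centres depend only on the data, so detailed balance holds.
        with np.errstate(invalid="ignore", divide="ignore"):
            pbar = self.k.sum(axis=1) / np.maximum(self.n.sum(axis=1), 1.0)
            num = ((self.k / np.maximum(self.n, 1.0) - pbar[:, None]) ** 2).mean(axis=1)
            den = np.maximum(pbar * (1 - pbar), 1e-4)
            f_hat = np.clip(num / den, 0.005, 0.95)
        centre = logit(f_hat)
        self.rj_centre = centre - np.median(centre)

        self.ll = _loglik(self.k, self.n, self.p, self._eta())  # (L, J)

    def _eta(self) -> np.ndarray:
        return (self.alpha * self.delta)[:, None] + self.beta[None, :]

    # -- single-sweep updates ------------------------------------------------

    def update_p(self) -> float:
        z = logit(self.p) + self.rng.normal(0, self.sd_p, self.L)
        p_new = expit(z)
        ll_new = _loglik(self.k, self.n, p_new, self._eta())
        # uniform prior on p; symmetric proposal on logit scale needs the
        # Jacobian log p(1-p) of the transform
        log_r = (
            ll_new.sum(axis=1)
            - self.ll.sum(axis=1)
            + np.log(p_new * (1 - p_new))
            - np.log(self.p * (1 - self.p))
        )
        acc = np.log(self.rng.random(self.L)) < log_r
        self.p[acc] = p_new[acc]
        self.ll[acc] = ll_new[acc]
        return float(acc.mean())

    def update_alpha(self) -> float:
        idx = self.delta
        if not idx.any():
            return math.nan
        a_new = self.alpha.copy()
        a_new[idx] += self.rng.normal(0, self.sd_alpha, int(idx.sum()))
        eta_new = (a_new * self.delta)[:, None] + self.beta[None, :]
        ll_new = _loglik(self.k, self.n, self.p, eta_new)
        log_r = (
            ll_new.sum(axis=1)
            - self.ll.sum(axis=1)
            - (a_new**2 - self.alpha**2) / (2 * _ALPHA_SD**2)
        )
        acc = idx & (np.log(self.rng.random(self.L)) < log_r)
        self.alpha[acc] = a_new[acc]
        self.ll[acc] = ll_new[acc]
        return float(acc[idx].mean())

    def update_beta(self) -> float:
        n_acc = 0
        for j in range(self.J):
            b_new = self.beta[j] + self.rng.normal(0, self.sd_beta)
            eta_j = self.alpha * self.delta + b_new
            ll_new_j = _loglik(
                self.k[:, j : j + 1], self.n[:, j : j + 1], self.p, eta_j[:, None]
            )[:, 0]
            log_r = (
                ll_new_j.sum()
                - self.ll[:, j].sum()
                - ((b_new - _BETA_MEAN) ** 2 - (self.beta[j] - _BETA_MEAN) ** 2)
                / (2 * _BETA_SD**2)
            )
            if math.log(self.rng.random()) < log_r:
                self.beta[j] = b_new
                self.ll[:, j] = ll_new_j
                n_acc += 1
        return n_acc / self.J

    def update_delta(self) -> None:
        """Reversible-jump birth/death of (delta_i, alpha_i), all loci."""
        if math.isinf(self.cfg.prior_odds):
            return
        births = ~self.delta
        a_prop = np.where(
            births, self.rj_centre + self.rng.normal(0, self.sd_rj, self.L), 0.0
        )
        eta_new = (np.where(births, a_prop, 0.0))[:, None] + self.beta[None, :]
        ll_new = _loglik(self.k, self.n, self.p, eta_new)
        d_ll = ll_new.sum(axis=1) - self.ll.sum(axis=1)

        log_prior_a = -0.5 * np.log(2 * np.pi * _ALPHA_SD**2) - a_prop**2 / (
            2 * _ALPHA_SD**2
        )
        a_curr = self.alpha
        log_prior_curr = -0.5 * np.log(2 * np.pi * _ALPHA_SD**2) - a_curr**2 / (
            2 * _ALPHA_SD**2
        )
        log_q_prop = -0.5 * np.log(2 * np.pi * self.sd_rj**2) - (
            a_prop - self.rj_centre
        ) ** 2 / (2 * self.sd_rj**2)
        log_q_curr = -0.5 * np.log(2 * np.pi * self.sd_rj**2) - (
            a_curr - self.rj_centre
        ) ** 2 / (2 * self.sd_rj**2)

        log_r = np.where(
            births,
            d_ll + log_prior_a + self.log_incl_prior - log_q_prop,
            d_ll - log_prior_curr - self.log_incl_prior + log_q_curr,
        )
        acc = np.log(self.rng.random(self.L)) < log_r
        new_delta = np.where(acc, births, self.delta)
        self.alpha = np.where(acc, np.where(births, a_prop, 0.0), self.alpha)
        self.delta = new_delta
        self.ll[acc] = ll_new[acc]

    def sweep(self) -> tuple[float, float, float]:
        acc_p = self.update_p()
        acc_a = self.update_alpha()
        acc_b = self.update_beta()
        self.update_delta()
        return acc_p, acc_a, acc_b

    # -- pilot tuning --------------------------------------------------------

    def tune(self) -> None:
        target_lo, target_hi = 0.25, 0.45
        last = (math.nan, math.nan, math.nan)
        for _ in range(self.cfg.n_pilot):
            accs = np.array(
                [self.sweep() for _ in range(self.cfg.pilot_len)], dtype=float
            )
            mean_acc = [
                float(np.mean(col[~np.isnan(col)])) if (~np.isnan(col)).any() else math.nan
                for col in accs.T
            ]
            last = tuple(mean_acc)
            for rate, attr in zip(mean_acc, ("sd_p", "sd_alpha", "sd_beta")):
                if math.isnan(rate):
                    continue
                if rate < target_lo:
                    setattr(self, attr, getattr(self, attr) * 0.7)
                elif rate > target_hi:
                    setattr(self, attr, getattr(self, attr) * 1.4)
        rates = [r for r in last if not math.isnan(r)]
        if rates and not all(0.1 <= r <= 0.6 for r in rates):
            logger.warning(
                "pilot adaptation finished outside [0.1, 0.6] acceptance "
                "(rates %s); proceeding with last tuning",
                [f"{r:.2f}" for r in rates],
            )


def fit(counts: AlleleCountTable, cfg: McmcConfig) -> PosteriorSummary:
    """Run the reversible-jump chain and summarise the posterior.

    Loci monomorphic across every cohort are excluded up front (their
    likelihood carries no information about F) with a logged count; their
    rows do not appear in the returned summary. The run is fully
    reproducible given ``cfg.seed``.
    """
    if counts.n_cohorts < 2:
        raise ValueError("fit needs at least two cohorts")
    poly = ~(
        (counts.n_a2.sum(axis=0) == 0)
        | (counts.n_a2.sum(axis=0) == counts.n_total.sum(axis=0))
    )
    n_excl = int((~poly).sum())
    if n_excl:
        logger.info("fit: excluding %d monomorphic loci", n_excl)
        counts = counts.subset_loci([l.id for l, k in zip(counts.loci, poly) if k])
    if counts.n_loci == 0:
        raise ValueError("no polymorphic loci to fit")

    rng = np.random.default_rng(cfg.seed)
    chain = _Chain(counts, cfg, rng)
    chain.tune()

    n_kept = 0
    incl_sum = np.zeros(chain.L)
    fst_sum = np.zeros(chain.L)
    alpha_sum = np.zeros(chain.L)
    for it in range(cfg.n_iter):
        chain.sweep()
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_kept += 1
            incl_sum += chain.delta
            f = np.clip(expit(chain._eta()), _F_EPS, 1 - _F_EPS)
            fst_sum += f.mean(axis=1)
            alpha_sum += np.where(chain.delta, chain.alpha, 0.0)

    p_incl = incl_sum / n_kept
    return PosteriorSummary(
        loci=list(counts.loci),
        p_incl=p_incl,
        q=q_values(p_incl),
        fst_mean=fst_sum / n_kept,
        alpha_mean=alpha_sum / n_kept,
        n_excluded_monomorphic=n_excl,
        config=cfg,
    )
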