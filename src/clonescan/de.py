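"""Empirical-Bayes negative-binomial two-condition differential expression.

Per gene, counts are modelled as negative binomial with a gene dispersion
estimated by moments and a Beta prior on the NB probability parameter
fitted by moments across genes. The marginal likelihood of a gene under
equal expression (all samples share one draw of the probability parameter)
and under differential expression (one independent draw per condition) has
closed beta-negative-binomial form; an EM over the mixing proportion
yields the posterior probability of differential expression (PPDE). A
selected set is reported together with its Bayesian FDR — the mean
posterior equal-expression probability over the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "median_ratio_size_factors", "fit_ppde", "select_de"]

_VAR_FLOOR = 1e-8
_R_MIN, _R_MAX = 0.05, 1e6


@dataclass
class DEResult:
    genes: list[str]
    ppde: np.ndarray  # per-gene posterior probability of DE
    pi_de: float  # estimated DE mixing proportion
    size_factors: np.ndarray
    alpha: float
    beta: float
    selected: list[str] = field(default_factory=list)
    bayesian_fdr: float = float("nan")
    converged: bool = True
    log_likelihood: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {"gene": self.genes, "ppde": self.ppde, "selected": [g in sel for g in self.genes]}
        ).set_index("gene")


def median_ratio_size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over genes with
    all-positive counts. With none present, ``pseudo_reference=True``
    falls back to adding one pseudo-count; otherwise an error is raised.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene with all-positive counts; re-run with pseudo_reference=True"
            )
        mat = mat + 1.0
        positive = np.ones(mat.shape[0], dtype=bool)
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _hyperparameters(q: np.ndarray) -> tuple[float, float]:
    """Beta(alpha, beta) fitted by moments to per-gene probability estimates."""
    q = np.clip(q, 1e-4, 1.0 - 1e-4)
    m, v = float(np.mean(q)), float(np.var(q))
    v = min(max(v, 1e-6), m * (1.0 - m) * 0.999)
    common = m * (1.0 - m) / v - 1.0
    return max(m * common, 1e-2), max((1.0 - m) * common, 1e-2)


def fit_ppde(
    counts: pd.DataFrame,
    conditions: list[str],
    size_factors: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    ppde_threshold: float = 1.0 - 1e-5,
    fdr_cap: float = 0.05,
    dispersion_prior_df: float = 4.0,
) -> DEResult:
    """Fit the equal/differential expression mixture and compute PPDE.

    ``conditions`` labels each sample column; exactly two distinct
    conditions are required, each with >= 2 replicates. The per-gene NB
    size is a method-of-moments estimate from within-condition
    variability, shrunk toward the across-gene median with
    ``dispersion_prior_df`` pseudo-degrees of freedom (within-condition
    moments keep the equal-expression model honest for truly differential
    genes; pooled moments would absorb the condition effect into the
    dispersion). EM runs over the mixing proportion with the
    observed-data log-likelihood asserted non-decreasing; non-convergence
    returns the last iterate flagged.
    """
    labels = sorted(set(conditions))
    if len(labels) != 2:
        raise ValueError("exactly two conditions required")
    cond = np.array(conditions)
    for lab in labels:
        if (cond == lab).sum() < 2:
            raise ValueError(f"condition {lab} needs >= 2 replicates")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts, pseudo_reference=True)
    s = np.asarray(size_factors, dtype=float)
    x = counts.to_numpy(dtype=float)
    norm = x / s[None, :]
    mean = norm.mean(axis=1)

    # dispersion phi with Var = mu + phi mu^2, pooled over within-condition moments
    num = np.zeros(x.shape[0])
    den = 0.0
    for lab in labels:
        cols = np.flatnonzero(cond == lab)
        m = norm[:, cols].mean(axis=1)
        v = norm[:, cols].var(axis=1, ddof=1)
        phi_c = (v - m) / np.maximum(m, _VAR_FLOOR) ** 2
        num += (len(cols) - 1) * phi_c
        den += len(cols) - 1
    phi_hat = np.clip(num / den, 0.0, None)
    phi_prior = max(float(np.median(phi_hat)), 1e-3)
    phi = (den * phi_hat + dispersion_prior_df * phi_prior) / (den + dispersion_prior_df)
    r = np.clip(1.0 / np.maximum(phi, 1e-6), _R_MIN, _R_MAX)

    # per-sample size: r_gj = r_g * s_j, so the NB mean scales with the library
    r_mat = r[:, None] * s[None, :]
    q_hat = r / np.maximum(r + mean, _VAR_FLOOR)
    alpha, beta = _hyperparameters(q_hat)

    def group_logmarginal(cols: np.ndarray) -> np.ndarray:
        rs = r_mat[:, cols].sum(axis=1)
        xs = x[:, cols].sum(axis=1)
        return betaln(alpha + rs, beta + xs) - betaln(alpha, beta)

    all_cols = np.arange(x.shape[1])
    c1 = np.flatnonzero(cond == labels[0])
    c2 = np.flatnonzero(cond == labels[1])
    log_f0 = group_logmarginal(all_cols)
    log_f1 = group_logmarginal(c1) + group_logmarginal(c2)

    pi = 0.1
    last_ll = -np.inf
    converged = False
    ppde = np.full(x.shape[0], pi)
    for _ in range(max_iter):
        a = np.log(pi) + log_f1
        b = np.log1p(-pi) + log_f0
        m = np.maximum(a, b)
        log_mix = m + np.log(np.exp(a - m) + np.exp(b - m))
        ll = float(log_mix.sum())
        assert ll >= last_ll - 1e-8, "EM log-likelihood decreased"
        ppde = np.exp(a - log_mix)
        if abs(ll - last_ll) < tol:
            converged = True
            last_ll = ll
            break
        last_ll = ll
        pi = float(np.clip(ppde.mean(), 1e-6, 1.0 - 1e-6))
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    result = DEResult(
        genes=list(counts.index),
        ppde=ppde,
        pi_de=pi,
        size_factors=s,
        alpha=alpha,
        beta=beta,
        converged=converged,
        log_likelihood=last_ll,
    )
    select_de(result, ppde_threshold=ppde_threshold, fdr_cap=fdr_cap)
    return result


def select_de(
    result: DEResult, ppde_threshold: float = 1.0 - 1e-5, fdr_cap: float = 0.05
) -> list[str]:
    """Select genes at the PPDE threshold, capped at the Bayesian FDR.

    Genes with PPDE >= threshold are selected; if their mean posterior
    equal-expression probability exceeds ``fdr_cap`` the selection is
    shrunk by descending PPDE until it satisfies the cap. Updates and
    returns ``result.selected``.
    """
    order = np.argsort(-result.ppde, kind="stable")
    ppde_sorted = result.ppde[order]
    k = int((ppde_sorted >= ppde_threshold).sum())
    while k > 0 and float(np.mean(1.0 - ppde_sorted[:k])) > fdr_cap:
        k -= 1
    idx = order[:k]
    result.selected = [result.genes[i] for i in sorted(idx)]
    result.bayesian_fdr = float(np.mean(1.0 - ppde_sorted[:k])) if k else float("nan")
    return result.selected
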