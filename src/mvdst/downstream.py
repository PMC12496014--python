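"""Spatial-domain identification, evaluation metrics, and DE calling.

Clustering is plain K-means on the learned latent features.  Differential
expression is a per-domain one-vs-rest Wilcoxon rank-sum test: the exact
permutation distribution of the rank-sum statistic (tie-aware, computed by
a generating-function recursion) is used when both groups have at most
``EXACT_MAX`` members, and the normal approximation with tie correction
otherwise.  P-values are Benjamini-Hochberg adjusted within each domain and
records are reported only when they clear the fraction-expressed, fold
change, and FDR thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    davies_bouldin_score,
    silhouette_score,
)
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, ParameterError
from .io_preprocess import SRTDataset

__all__ = [
    "DomainLabels",
    "DEGRecord",
    "EvaluationReport",
    "identify_domains",
    "evaluate_mse",
    "evaluate_clustering",
    "differential_expression",
    "exact_ranksum_pvalue",
    "wilcoxon_rank_sum",
]

EXACT_MAX = 25  # exact permutation distribution up to this group size


@dataclass
class DomainLabels:
    """Per-spot integer domain assignment in [0, k)."""

    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.max() >= self.k:
            raise ContractError("label exceeds domain count")


@dataclass
class DEGRecord:
    gene_id: str
    domain: int
    log2_fold_change: float
    pct_in_domain: float
    p_value: float
    fdr: float


@dataclass
class EvaluationReport:
    """Metrics that could be computed; absent metrics are None, never NaN."""

    mse: float | None = None
    ari: float | None = None
    silhouette: float | None = None
    davies_bouldin: float | None = None

    def to_dict(self) -> dict:
        return {
            key: val
            for key, val in (
                ("mse", self.mse),
                ("ari", self.ari),
                ("silhouette", self.silhouette),
                ("davies_bouldin", self.davies_bouldin),
            )
            if val is not None
        }


def identify_domains(
    Z: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> DomainLabels:
    """K-means on latent features with seeded restarts (best inertia kept)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} must lie in [1, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return DomainLabels(labels=labels, k=k, seed=seed)


def evaluate_mse(clean: np.ndarray, denoised: np.ndarray) -> float:
    """Mean over spots of the squared row-difference norm."""
    clean = np.asarray(clean, dtype=float)
    denoised = np.asarray(denoised, dtype=float)
    if clean.shape != denoised.shape:
        raise ContractError(f"shape mismatch {clean.shape} vs {denoised.shape}")
    diff = clean - denoised
    return float(np.sum(diff * diff) / clean.shape[0])


def evaluate_clustering(
    labels: DomainLabels | np.ndarray,
    truth: np.ndarray | None = None,
    features: np.ndarray | None = None,
) -> EvaluationReport:
    """ARI against truth (if given) plus SC/DBI on features (if given)."""
    lab = labels.labels if isinstance(labels, DomainLabels) else np.asarray(labels)
    report = EvaluationReport()
    if truth is not None:
        report.ari = float(adjusted_rand_score(np.asarray(truth), lab))
    if features is not None:
        features = np.asarray(features, dtype=float)
        if len(np.unique(lab)) < 2:
            warnings.warn(
                "silhouette/DBI undefined for a single cluster; omitted",
                stacklevel=2,
            )
        else:
            report.silhouette = float(silhouette_score(features, lab))
            report.davies_bouldin = float(davies_bouldin_score(features, lab))
    return report


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value over all group assignments.

    Uses midranks, so ties are handled exactly.  The null distribution of
    the group-1 rank sum S is computed by a subset-sum recursion over the
    pooled (doubled, hence integer) midranks; the two-sided p-value is
    P(|S - E[S]| >= |s_obs - E[S]|) under uniform assignment.  Integer
    arithmetic throughout, so the result matches exhaustive enumeration
    exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)  # midranks are k/2
    s_obs2 = int(ranks2[:n1].sum())
    mu2 = n1 * (n1 + n2 + 1)  # doubled mean rank sum
    dev_obs = abs(s_obs2 - mu2)

    # count[k][s] = number of k-subsets of the pooled ranks with doubled sum s
    counts = [dict() for _ in range(n1 + 1)]
    counts[0][0] = 1
    for r in ranks2.tolist():
        for k in range(min(n1, len(ranks2)) - 1, -1, -1):
            if not counts[k]:
                continue
            tgt = counts[k + 1]
            for s, c in counts[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    extreme = sum(
        c for s, c in counts[n1].items() if abs(s - mu2) >= dev_obs
    )
    return extreme / comb(n1 + n2, n1)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value: exact for small groups, else asymptotic.

    The asymptotic branch applies the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX and len(y) <= EXACT_MAX:
        return exact_ranksum_pvalue(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values identical: no evidence either way
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def differential_expression(
    ds: SRTDataset,
    labels: DomainLabels | np.ndarray,
    pct_min: float = 0.8,
    lfc_min: float = 2.0,
    fdr_max: float = 0.05,
    eps: float = 1e-9,
) -> list[DEGRecord]:
    """One-vs-rest Wilcoxon DE per domain with pct/log2FC/FDR filters.

    Fold change is computed on de-logged (expm1) means with pseudocount
    ``eps``; "expressed" means nonzero after normalization.  A record is
    emitted iff ``pct_in_domain > pct_min`` and ``|log2FC| >= lfc_min`` and
    ``fdr <= fdr_max``.
    """
    if not ds.normalized:
        raise ParameterError("differential_expression requires normalized data")
    lab = labels.labels if isinstance(labels, DomainLabels) else np.asarray(labels)
    if len(lab) != ds.n_spots:
        raise ContractError("labels length does not match spot count")
    X = ds.dense_expression()
    delogged = np.expm1(X)
    records: list[DEGRecord] = []
    for domain in np.unique(lab):
        mask = lab == domain
        n_in = int(mask.sum())
        if n_in < 2:
            raise ParameterError(f"domain {domain} has fewer than 2 spots")
        if (~mask).sum() < 2:
            raise ParameterError(f"complement of domain {domain} has fewer than 2 spots")
        pvals = np.array(
            [wilcoxon_rank_sum(X[mask, j], X[~mask, j]) for j in range(ds.n_genes)]
        )
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        pct_in = (X[mask] != 0).mean(axis=0)
        mean_in = delogged[mask].mean(axis=0)
        mean_out = delogged[~mask].mean(axis=0)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        selected = (pct_in > pct_min) & (np.abs(lfc) >= lfc_min) & (fdrs <= fdr_max)
        for j in np.flatnonzero(selected):
            records.append(
                DEGRecord(
                    gene_id=ds.gene_ids[j],
                    domain=int(domain),
                    log2_fold_change=float(lfc[j]),
                    pct_in_domain=float(pct_in[j]),
                    p_value=float(pvals[j]),
                    fdr=float(fdrs[j]),
                )
            )
    return records
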