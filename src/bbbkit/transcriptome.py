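"""Differential expression, deletion-region control, PCA and enrichment.

The DE stage applies the negative-binomial model standard for RNA-seq
counts: median-of-ratios size factors, a method-of-moments NB dispersion
per gene moderated against a pooled (trend) estimate, and a Wald test on
the log fold change (DEL/WT). It is a deliberately minimal in-repo test
meant to let synthetic counts flow end-to-end; an externally produced
DEG table (e.g. from a full DESeq2 fit) can be supplied instead for real
data and enters the same downstream filters.

Significant DEGs are defined by the strict rule FDR < 0.01 and
baseMean > 100, then split into up- (FC > 2) and down-regulated
(FC < 0.5) lists. Genes inside the hemizygous deletion region act as
positive controls: every one of them detected as significant is expected
to be down-regulated. Gene-set enrichment is a one-sided hypergeometric
(Fisher) upper-tail test with Benjamini-Hochberg correction across terms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix

__all__ = [
    "size_factors",
    "nb_de_test",
    "filter_degs",
    "split_by_fold",
    "FoldSplit",
    "deletion_region_check",
    "DeletionCheck",
    "pca_samples",
    "enrich",
]

_MIN_DISPERSION = 1e-8
_MAX_DISPERSION = 10.0
#: genes with normalised mean above this in both groups feed the pooled
#: dispersion estimate (low counts make moment estimates unstable)
_POOL_MEAN_MIN = 5.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Ratios are taken against the per-gene geometric mean over genes with
    no zero counts; a group of all-zero libraries is rejected.
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr.sum(axis=0) == 0):
        raise ValueError("a library has zero total counts")
    all_pos = np.all(arr > 0, axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(arr[all_pos])
    log_geo = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def nb_de_test(cm: CountMatrix, dispersion_mode: str = "max") -> pd.DataFrame:
    """Minimal NB Wald test for DEL-vs-WT differential expression.

    Per gene: normalised group means, a Bessel-corrected method-of-
    moments dispersion pooled over both groups, and a Wald z for the log
    fold change with variance sum_g (1/mu_g + alpha)/n_g. Gene-wise
    dispersions at small n are extremely noisy, so the working value is
    ``max(gene-wise, pooled-over-genes)`` by default ("max" mode guards
    against under-dispersion artefacts; "pooled" uses the trend value for
    every gene, "genewise" uses the raw per-gene estimate).

    Returns a DataFrame indexed by gene with columns base_mean, log2fc
    (DEL/WT), lfc_se, stat, pvalue, fdr, dispersion and in_deletion
    (False when no truth annotation is attached).
    """
    wt = cm.samples_in("WT")
    dl = cm.samples_in("DEL")
    if len(wt) < 2 or len(dl) < 2:
        raise ValueError("need at least 2 samples per group")
    sf = size_factors(cm.counts)
    y = cm.counts.to_numpy(dtype=float) / sf.to_numpy()
    iw = [cm.counts.columns.get_loc(c) for c in wt]
    idl = [cm.counts.columns.get_loc(c) for c in dl]
    yw, yd = y[:, iw], y[:, idl]
    nw, nd = len(iw), len(idl)
    mw, md = yw.mean(axis=1), yd.mean(axis=1)

    ssw = ((yw - mw[:, None]) ** 2).sum(axis=1)
    ssd = ((yd - md[:, None]) ** 2).sum(axis=1)
    num = ssw - (nw - 1) * mw + ssd - (nd - 1) * md
    den = (nw - 1) * mw ** 2 + (nd - 1) * md ** 2
    pool_ok = (mw > _POOL_MEAN_MIN) & (md > _POOL_MEAN_MIN)
    if pool_ok.any() and den[pool_ok].sum() > 0:
        alpha_pool = max(num[pool_ok].sum() / den[pool_ok].sum(), _MIN_DISPERSION)
    else:
        alpha_pool = _MIN_DISPERSION
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = np.where(den > 0, num / den, alpha_pool)
    alpha_gene = np.clip(alpha_gene, _MIN_DISPERSION, _MAX_DISPERSION)
    if dispersion_mode == "max":
        alpha = np.maximum(alpha_gene, alpha_pool)
    elif dispersion_mode == "pooled":
        alpha = np.full_like(alpha_gene, alpha_pool)
    elif dispersion_mode == "genewise":
        alpha = alpha_gene
    else:
        raise ValueError("dispersion_mode must be 'max', 'pooled' or 'genewise'")

    mw_ = np.maximum(mw, _MIN_DISPERSION)
    md_ = np.maximum(md, _MIN_DISPERSION)
    se2 = (1.0 / mw_ + alpha) / nw + (1.0 / md_ + alpha) / nd
    lfc_ln = np.log(md_ / mw_)
    z = lfc_ln / np.sqrt(se2)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mw == 0) & (md == 0)
    pvalue[both_zero] = 1.0
    z[both_zero] = 0.0
    fdr = multipletests(pvalue, method="fdr_bh")[1]

    in_deletion = (cm.truth["in_deletion"].to_numpy()
                   if cm.truth is not None and "in_deletion" in cm.truth
                   else np.zeros(len(cm.counts), dtype=bool))
    log2fc = np.log2(np.maximum(md, 0.5) / np.maximum(mw, 0.5))
    return pd.DataFrame({
        "base_mean": y.mean(axis=1),
        "log2fc": log2fc,
        "lfc_se": np.sqrt(se2) / np.log(2),
        "stat": z,
        "pvalue": pvalue,
        "fdr": fdr,
        "dispersion": alpha,
        "in_deletion": in_deletion,
    }, index=cm.counts.index)


def filter_degs(table: pd.DataFrame, fdr_max: float = 0.01,
                base_mean_min: float = 100.0) -> pd.DataFrame:
    """Significant DEGs by the strict rule fdr < fdr_max AND base_mean > base_mean_min."""
    return table[(table["fdr"] < fdr_max) & (table["base_mean"] > base_mean_min)]


class FoldSplit(NamedTuple):
    up: pd.DataFrame        # FC > 2   (log2fc > 1)
    down: pd.DataFrame      # FC < 0.5 (log2fc < -1)
    unsplit: pd.DataFrame   # significant but between the fold cuts


def split_by_fold(degs: pd.DataFrame, fold_up: float = 2.0,
                  fold_down: float = 0.5) -> FoldSplit:
    """Split significant DEGs by strict fold-change cuts."""
    lfc_up, lfc_down = np.log2(fold_up), np.log2(fold_down)
    up = degs[degs["log2fc"] > lfc_up]
    down = degs[degs["log2fc"] < lfc_down]
    unsplit = degs[(degs["log2fc"] >= lfc_down) & (degs["log2fc"] <= lfc_up)]
    return FoldSplit(up, down, unsplit)


@dataclass
class DeletionCheck:
    """Positive-control summary for deletion-region genes."""

    applicable: bool
    fraction_down: float | None
    n_significant: int
    per_gene: pd.DataFrame


def deletion_region_check(degs: pd.DataFrame,
                          deletion_ids: Iterable[str]) -> DeletionCheck:
    """Fraction of significant deletion-region genes that are down-regulated.

    ``degs`` is a table of significant DEGs (after :func:`filter_degs`).
    With an empty deletion list, or none of its genes significant, the
    check is reported as not applicable rather than as 0 or 1.
    """
    ids = list(deletion_ids)
    if not ids:
        return DeletionCheck(False, None, 0, pd.DataFrame())
    present = degs.loc[degs.index.intersection(ids)].copy()
    if present.empty:
        return DeletionCheck(False, None, 0, present)
    down = present["log2fc"] < 0
    present["down_regulated"] = down
    return DeletionCheck(True, float(down.mean()), int(len(present)), present)


def pca_samples(cm: CountMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample-level PCA on log2(normalised count + 1), genes centred.

    Returns (variance fractions summing to 1, score table with one row
    per sample and columns PC1..PCk).
    """
    if cm.counts.shape[1] < 3:
        raise ValueError("need at least 3 samples for a sample PCA")
    sf = size_factors(cm.counts)
    x = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy() + 1.0).T
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("zero-variance count matrix")
    fractions = var / total
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return fractions, pd.DataFrame(scores, index=cm.counts.columns, columns=cols)


def enrich(gene_set: Iterable[str], term_to_genes: Mapping[str, Iterable[str]],
           universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene set against terms.

    For a universe of M genes, a query of n genes and a term annotating K
    universe genes with k of them in the query, the one-sided p is
    P(X >= k) for X ~ Hypergeom(M, K, n). Terms with no annotated
    universe genes get p = 1. BH adjustment is across all tested terms.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_set) & uni
    if not set(gene_set) <= uni:
        missing = sorted(set(gene_set) - uni)[:5]
        raise ValueError(f"query genes outside universe, e.g. {missing}")
    m_total, n_query = len(uni), len(query)
    rows = []
    for term, genes in term_to_genes.items():
        term_genes = set(genes) & uni
        k_term = len(term_genes)
        overlap = len(term_genes & query)
        p = 1.0 if k_term == 0 else float(
            stats.hypergeom.sf(overlap - 1, m_total, k_term, n_query))
        rows.append((term, overlap, k_term, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out.set_index("term")
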