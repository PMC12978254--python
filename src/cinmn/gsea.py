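"""Pseudobulk aggregation, MN correlation, and preranked GSEA.

Single-cell (or single-nucleus) counts are summed per (compartment, sample)
into pseudobulk profiles, cross-sample normalized within each compartment,
and correlated gene-by-gene with tumor MN scores; the Pearson coefficient
R_p then serves as the rank metric for preranked gene-set enrichment.

The preranked GSEA here is the classic weighted Kolmogorov-Smirnov running
sum: genes are ordered by the metric, hits advance the running statistic in
proportion to |metric|^weight and misses retreat it uniformly; the
enrichment score (ES) is the largest signed deviation.  The null is built by
gene-label permutation (the only exchangeable unit for preranked input), the
normalized ES divides by the mean |null ES| of matching sign, nominal p uses
the unbiased (count+1)/(B+1) permutation estimator, and FDR q follows the
standard positive/negative pooling.  A second pass
(:func:`pathway_group_enrichment`) treats whole gene sets as items ranked by
their first-pass NES to ask whether a named group of pathways is itself
enriched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dependence import size_factors

__all__ = [
    "pseudobulk_aggregate",
    "correlate_with_mn",
    "enrichment_score",
    "preranked_gsea",
    "pathway_group_enrichment",
    "dge_rank_metric",
]


def pseudobulk_aggregate(
    cell_counts: pd.DataFrame,
    cell_compartment: pd.Series,
    cell_sample: pd.Series,
    normalize: bool = True,
) -> dict[str, pd.DataFrame]:
    """Sum raw counts per (compartment, sample); optionally normalize.

    ``cell_counts`` is genes x cells; the two Series map cell -> compartment
    and cell -> sample.  Aggregation preserves the total count of every
    (compartment, sample) group; normalization is median-of-ratios across
    samples within each compartment.
    """
    cols = cell_counts.columns
    comp = cell_compartment.loc[cols]
    samp = cell_sample.loc[cols]
    out = {}
    for c in pd.unique(comp):
        sub = cell_counts.loc[:, (comp == c).to_numpy()]
        agg = sub.T.groupby(samp.loc[sub.columns]).sum().T
        if normalize:
            agg = agg / size_factors(agg)
        out[c] = agg
    return out


def correlate_with_mn(pseudobulk: pd.DataFrame, mn_scores: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with sample MN scores.

    Requires >= 3 samples; genes with zero variance get NaN (reported
    missing, not zero).  Returns a DataFrame with ``r`` and ``p``.
    """
    samples = [s for s in pseudobulk.columns if s in mn_scores.index]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with MN scores")
    X = pseudobulk[samples].to_numpy(float)
    y = mn_scores[samples].to_numpy(float)
    n = len(samples)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.where(sx > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return pd.DataFrame({"r": r, "p": p}, index=pseudobulk.index)


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _order_metric(ranked: pd.Series):
    """Descending metric order; ties broken by stable gene-name order."""
    ranked = ranked[np.isfinite(ranked.to_numpy(float))]
    df = pd.DataFrame({"m": ranked.to_numpy(float)}, index=ranked.index)
    df = df.sort_index(kind="mergesort").sort_values("m", ascending=False, kind="mergesort")
    return df.index.to_numpy(), df["m"].to_numpy()


def _es_from_positions(pos, absw, W, n, m):
    """ES given sorted hit positions (any leading dims) and their weights."""
    cum = np.cumsum(absw, axis=-1)
    k = np.arange(m)
    miss = (pos - k) / (n - m) if n > m else np.zeros_like(pos, dtype=float)
    dev_after = cum / W - miss
    dev_before = (cum - absw) / W - miss
    up = dev_after.max(axis=-1)
    dn = dev_before.min(axis=-1)
    return np.where(up >= -dn, up, dn)


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Weighted KS enrichment score of ``gene_set`` in a ranked list."""
    genes, metric = _order_metric(ranked)
    hit = np.isin(genes, list(gene_set))
    m = int(hit.sum())
    n = len(genes)
    if m == 0 or m == n:
        raise ValueError("gene set must hit a strict subset of the ranked genes")
    pos = np.where(hit)[0]
    absw = np.abs(metric[pos]) ** weight
    W = absw.sum()
    if W == 0:  # all-zero metric at the hits: fall back to unweighted steps
        absw = np.ones_like(absw)
        W = float(m)
    return float(_es_from_positions(pos, absw, W, n, m))


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA over a ranked gene list.

    Returns a DataFrame indexed by set name with size, ``es``, ``nes``,
    nominal ``p`` and FDR ``q``.  Sets overlapping the ranked genes in fewer
    than ``min_size`` genes are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    genes, metric = _order_metric(ranked)
    n = len(genes)
    absm = np.abs(metric) ** weight

    rows = []
    null_nes_pos, null_nes_neg = [], []
    for name, members in gene_sets.items():
        hit = np.isin(genes, list(members))
        m = int(hit.sum())
        if m < min_size or m >= n:
            warnings.warn(f"set {name!r}: {m} usable genes; skipped")
            continue
        pos = np.where(hit)[0]
        w = absm[pos]
        W = w.sum() if w.sum() > 0 else float(m)
        es = float(_es_from_positions(pos, w if w.sum() > 0 else np.ones(m), W, n, m))

        # gene-label permutation null: random positions of an m-gene set
        r = rng.random((n_perm, n))
        perm_pos = np.sort(np.argpartition(r, m - 1, axis=1)[:, :m], axis=1)
        pw = absm[perm_pos]
        pW = pw.sum(axis=1)
        zero = pW == 0
        if zero.any():
            pw[zero] = 1.0
            pW[zero] = m
        null_es = _es_from_positions(perm_pos, pw, pW[:, None], n, m)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
            b = int((pos_null >= es).sum())
            p = (b + 1) / (len(pos_null) + 1)
        else:
            nes = es / mean_neg if np.isfinite(mean_neg) else np.nan
            b = int((neg_null <= es).sum())
            p = (b + 1) / (len(neg_null) + 1)
        with np.errstate(invalid="ignore"):
            null_nes_pos.append(pos_null / mean_pos if np.isfinite(mean_pos) else np.array([]))
            null_nes_neg.append(neg_null / mean_neg if np.isfinite(mean_neg) else np.array([]))
        rows.append(dict(name=name, size=m, es=es, nes=float(nes), p=float(p)))

    res = pd.DataFrame(rows).set_index("name") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "q"]
    )
    if len(res):
        res["q"] = _gsea_fdr(res["nes"].to_numpy(),
                             np.concatenate(null_nes_pos) if null_nes_pos else np.array([]),
                             np.concatenate(null_nes_neg) if null_nes_neg else np.array([]))
    return res


def _gsea_fdr(nes, null_pos, null_neg):
    """Standard GSEA FDR: pooled same-sign null vs observed NES tail ratio."""
    q = np.full(len(nes), np.nan)
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes < 0]
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            num = (null_pos >= v).mean() if len(null_pos) else np.nan
            den = (obs_pos >= v).mean() if len(obs_pos) else np.nan
        else:
            num = (null_neg <= v).mean() if len(null_neg) else np.nan
            den = (obs_neg <= v).mean() if len(obs_neg) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            q[i] = min(num / den, 1.0) if den and np.isfinite(num) else np.nan
    return q


def pathway_group_enrichment(
    gsea_results: pd.DataFrame,
    group_lists: dict[str, list],
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "nes",
) -> pd.DataFrame:
    """Meta-enrichment of named pathway groups over first-pass GSEA output.

    Gene sets become the ranked items (metric = first-pass NES by default)
    and each group of sets is tested exactly like a gene set, asking whether
    e.g. the interferon-response pathways cluster at one end of the NES
    ranking.
    """
    ranked = gsea_results[metric].dropna()
    return preranked_gsea(ranked, group_lists, n_perm=n_perm, seed=seed)


def dge_rank_metric(dge: pd.DataFrame, p_col: str = "padj", lfc_col: str = "log2_fc") -> pd.Series:
    """-log10(adjusted p) x sign(log2 FC), the DGE-based GSEA rank metric."""
    p = dge[p_col].to_numpy(float)
    p = np.clip(p, 1e-300, 1.0)
    out = pd.Series(-np.log10(p) * np.sign(dge[lfc_col].to_numpy(float)), index=dge.index)
    return out[np.isfinite(out)]
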