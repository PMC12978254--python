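"""MN-burden association models and expression signatures.

Links gene expression in an isogenic clone panel to the measured cGAS+ MN
burden (MN per 100 cells): per-gene linear mixed-effects models with random
intercepts for clone (and batch within clone, when replicated), selection of
the top genes most strongly positively associated with MN burden (the CIN^MN
signature), single-sample GSEA scoring of signatures, the myeloid:lymphoid
skew score, and derivation of compartment-exclusive marker signatures from
externally supplied pairwise differential-expression tables.

The MN burden is a clone-level covariate (each clone carries one measured
burden), so the reported p value for the MN effect uses between-clone degrees
of freedom (n_clones - 2) — the reference distribution a Satterthwaite-type
ANOVA would give for a cluster-constant fixed effect.  A Wald z at the
observation level would overstate significance badly at a dozen clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dependence import filter_genes, size_factors

__all__ = [
    "MnAssociation",
    "GeneSignature",
    "filter_and_normalize",
    "fit_mn_lmm",
    "fit_mn_lmm_matrix",
    "derive_cin_mn_signature",
    "ssgsea_score",
    "myeloid_lymphoid_skew",
    "derive_compartment_signatures",
]


@dataclass
class MnAssociation:
    """Per-gene MN-burden association from the mixed model."""

    gene: str
    slope: float  # expression units per MN%
    p: float
    var_clone: float
    var_batch: float
    var_resid: float
    fallback: bool = False  # True when the mixed fit degenerated to OLS


@dataclass
class GeneSignature:
    """Named, ordered gene list with optional per-gene selection statistics."""

    name: str
    genes: list[str]
    provenance: pd.DataFrame | None = None

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self):
        return len(self.genes)


def filter_and_normalize(
    counts: pd.DataFrame, min_total: int = 50, min_expressed_samples: int = 4
) -> pd.DataFrame:
    """Gene filters then log2(size-factor-normalized count + 1).

    The log2(x+1) of median-of-ratios-normalized counts serves as the
    variance-stabilized scale on which the mixed models run; at the depths
    retained by the >= ``min_total`` filter it is close to affine in log
    expression.
    """
    kept = filter_genes(counts, min_total=min_total, min_expressed_samples=min_expressed_samples)
    sf = size_factors(kept)
    return np.log2(kept / sf + 1.0)


def _between_clone_test(y, mn, clone):
    """Exact t test of the MN slope on clone means (df = n_clones - 2)."""
    df = pd.DataFrame({"y": y, "mn": mn, "clone": clone})
    cm = df.groupby("clone").mean()
    n = len(cm)
    if n < 3 or cm["mn"].nunique() < 2:
        return np.nan, np.nan
    x = cm["mn"].to_numpy()
    yy = cm["y"].to_numpy()
    xc = x - x.mean()
    slope = (xc * yy).sum() / (xc**2).sum()
    resid = yy - yy.mean() - slope * xc
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / (xc**2).sum())
    t = slope / se
    return slope, 2.0 * stats.t.sf(abs(t), n - 2)


def fit_mn_lmm(
    y: np.ndarray, mn: np.ndarray, clone: np.ndarray, batch: np.ndarray, gene: str = ""
) -> MnAssociation:
    """Mixed model  expression ~ MN + (1 | clone/batch)  for one gene.

    Random intercepts for clone and for batch nested in clone; the nested
    component is only estimated when some clone x batch cell holds more than
    one observation (with singletons it is confounded with the residual).
    When MN is constant within clones, the MN-effect p comes from the exact
    between-clone t; otherwise from the Wald statistic of the mixed fit.
    A singular or non-convergent fit falls back to OLS with clone-clustered
    standard errors and is flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = pd.DataFrame({"y": np.asarray(y, float), "mn": mn, "clone": clone, "batch": batch})
    if d["clone"].nunique() < 2 or d["batch"].nunique() < 2:
        raise ValueError("need >= 2 clones and >= 2 batches")
    replicated = (d.groupby(["clone", "batch"]).size() > 1).any()
    mn_clone_constant = (d.groupby("clone")["mn"].nunique() == 1).all()

    slope = p = np.nan
    var_clone = var_batch = var_resid = np.nan
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if replicated:
                model = smf.mixedlm(
                    "y ~ mn", d, groups=d["clone"], re_formula="1",
                    vc_formula={"batch": "0 + C(batch)"},
                )
            else:
                model = smf.mixedlm("y ~ mn", d, groups=d["clone"], re_formula="1")
            fit = model.fit(reml=True)
        slope = float(fit.fe_params["mn"])
        var_clone = float(np.asarray(fit.cov_re)[0, 0])
        var_batch = float(fit.vcomp[0]) if replicated and len(fit.vcomp) else 0.0
        var_resid = float(fit.scale)
        if mn_clone_constant:
            _, p = _between_clone_test(d["y"], d["mn"], d["clone"])
        else:
            p = float(fit.pvalues["mn"])
        if not np.isfinite(slope) or not np.isfinite(p):
            raise ValueError("non-finite mixed fit")
    except Exception:
        fallback = True
        ols = smf.ols("y ~ mn", d).fit(cov_type="cluster", cov_kwds={"groups": d["clone"]})
        slope = float(ols.params["mn"])
        p = float(ols.pvalues["mn"])
        var_resid = float(ols.scale)
        var_clone = var_batch = 0.0
    return MnAssociation(gene, slope, p, var_clone, var_batch, var_resid, fallback)


def _fast_balanced_lmm(expr: pd.DataFrame, mn, clone):
    """Closed-form clone-level fit for the common balanced design.

    With MN constant within clones and equal observations per clone, the
    mixed model's GLS slope equals OLS on clone means and the between-clone
    t is exact; variance components come from the one-way ANOVA moment
    estimators.  Used as the vectorized path of
    :func:`fit_mn_lmm_matrix`; agreement with the per-gene mixed fit is
    covered by tests.
    """
    d = pd.DataFrame({"clone": clone, "mn": mn})
    clones = pd.unique(d["clone"])
    n_per = d.groupby("clone").size()
    Y = expr.to_numpy()  # genes x samples
    cm = np.column_stack([Y[:, (d["clone"] == c).to_numpy()].mean(axis=1) for c in clones])
    x = d.groupby("clone")["mn"].first()[clones].to_numpy()
    nc = len(clones)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    slope = cm @ xc / sxx
    resid = cm - cm.mean(axis=1, keepdims=True) - slope[:, None] * xc[None, :]
    s2_between = (resid**2).sum(axis=1) / (nc - 2)
    se = np.sqrt(s2_between / sxx)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), nc - 2)
    # within-clone residual variance and MoM clone variance
    within_ss = np.zeros(Y.shape[0])
    for c in clones:
        cols = (d["clone"] == c).to_numpy()
        within_ss += ((Y[:, cols] - Y[:, cols].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    m = int(n_per.iloc[0])
    var_resid = within_ss / (Y.shape[1] - nc)
    var_clone = np.maximum(s2_between - var_resid / m, 0.0)
    return slope, p, var_clone, var_resid


def fit_mn_lmm_matrix(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Fit the MN mixed model for every gene of an expression matrix.

    ``meta`` needs columns ``mn``, ``clone``, ``batch`` indexed like the
    expression columns.  Balanced designs with clone-constant MN (the
    isogenic panel layout) use the exact closed-form clone-level fit;
    anything else falls through to the per-gene iterative fit.
    Returns a DataFrame indexed by gene with slope, p, variance components.
    """
    meta = meta.loc[expr.columns]
    mn, clone, batch = meta["mn"], meta["clone"], meta["batch"]
    d = pd.DataFrame({"clone": clone, "mn": mn})
    balanced = d.groupby("clone").size().nunique() == 1
    mn_const = (d.groupby("clone")["mn"].nunique() == 1).all()
    if balanced and mn_const and clone.nunique() >= 3:
        slope, p, var_clone, var_resid = _fast_balanced_lmm(expr, mn, clone)
        return pd.DataFrame(
            {"slope": slope, "p": p, "var_clone": var_clone,
             "var_batch": 0.0, "var_resid": var_resid, "fallback": False},
            index=expr.index,
        )
    rows = []
    for g in expr.index:
        a = fit_mn_lmm(expr.loc[g].to_numpy(), mn, clone, batch, gene=g)
        rows.append((a.slope, a.p, a.var_clone, a.var_batch, a.var_resid, a.fallback))
    return pd.DataFrame(
        rows, index=expr.index,
        columns=["slope", "p", "var_clone", "var_batch", "var_resid", "fallback"],
    )


def derive_cin_mn_signature(associations: pd.DataFrame, k: int = 70, name: str = "CIN_MN") -> GeneSignature:
    """Top-``k`` genes most strongly positively associated with MN burden.

    Restricted to positive slopes, ranked by ascending p with ties broken by
    larger slope.  Deterministic given the association table; warns when
    fewer than ``k`` positive-slope genes exist.
    """
    pos = associations[(associations["slope"] > 0) & np.isfinite(associations["p"])]
    ranked = pos.sort_values(["p", "slope"], ascending=[True, False], kind="mergesort")
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} positive-slope genes; signature shorter than {k}")
    top = ranked.head(k)
    return GeneSignature(name=name, genes=list(top.index), provenance=top)


def ssgsea_score(
    expr: pd.DataFrame,
    signature: GeneSignature | list[str],
    exponent: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Per sample, genes are ranked by expression (descending; ties broken by
    gene order for determinism) and the score is the sum over the list of the
    difference between the weighted in-set and uniform out-of-set empirical
    CDFs, with rank weights |r|^``exponent``.  When ``normalize`` the scores
    are divided by their range across samples (the method's standard
    normalization).  Signature genes absent from the matrix are dropped with
    a warning; the score is a rank statistic, invariant to any strictly
    monotone transform of the expression values.
    """
    genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
    present = [g for g in genes if g in expr.index]
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature genes absent from matrix; dropped")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    in_set = expr.index.isin(present).astype(float)
    n = len(expr.index)
    n_out = n - len(present)
    scores = {}
    vals = expr.to_numpy()
    for j, sample in enumerate(expr.columns):
        order = np.lexsort((np.arange(n), -vals[:, j]))  # descending, stable
        hits = in_set[order]
        ranks = np.arange(n, 0, -1, dtype=float)  # N at the top of the list
        w = np.where(hits > 0, ranks**exponent, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(1.0 - hits) / max(n_out, 1)
        scores[sample] = float((p_in - p_out).sum())
    out = pd.Series(scores, name=getattr(signature, "name", "ssgsea"))
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def myeloid_lymphoid_skew(myeloid_scores: pd.Series, lymphoid_scores: pd.Series) -> pd.Series:
    """My:Ly skew = myeloid signature score - lymphoid signature score."""
    out = myeloid_scores - lymphoid_scores
    out.name = "my_ly_skew"
    return out


def derive_compartment_signatures(
    pairwise_dge: dict[tuple[str, str], pd.DataFrame],
    cluster_compartment: dict[str, str],
    compartments: tuple[str, str] = ("myeloid", "lymphoid"),
    top_n: int = 50,
    alpha: float = 0.05,
) -> dict[str, GeneSignature]:
    """Compartment-exclusive marker signatures from pairwise DGE tables.

    ``pairwise_dge[(a, b)]`` holds gene, ``log2_fc``, ``padj`` for cluster
    ``a`` versus cluster ``b`` (the reverse orientation is inferred when only
    one is supplied).  A gene qualifies for compartment ``c`` iff it is
    significantly up (padj <= ``alpha``, lfc > 0) in *every* comparison of a
    ``c`` cluster against a non-``c`` cluster, and qualifies for no other
    compartment ("exclusively up-regulated").  Genes are ranked by their
    worst-case padj over the qualifying comparisons and the top ``top_n``
    kept per compartment.
    """
    tables = {}
    for (a, b), df in pairwise_dge.items():
        t = df.set_index("gene") if "gene" in df.columns else df
        tables[(a, b)] = t
        if (b, a) not in pairwise_dge:
            rev = t.copy()
            rev["log2_fc"] = -rev["log2_fc"]
            tables[(b, a)] = rev

    clusters = sorted(cluster_compartment)
    all_genes = sorted(set().union(*[set(t.index) for t in tables.values()]))
    qualifies: dict[str, dict[str, float]] = {}
    for c in compartments:
        own = [cl for cl in clusters if cluster_compartment[cl] == c]
        others = [cl for cl in clusters if cluster_compartment[cl] != c]
        if not own or not others:
            qualifies[c] = {}
            continue
        worst: dict[str, float] = {}
        for g in all_genes:
            worst_p = 0.0
            ok = True
            for i in own:
                for j in others:
                    t = tables.get((i, j))
                    if t is None or g not in t.index:
                        ok = False
                        break
                    row = t.loc[g]
                    if not (row["padj"] <= alpha and row["log2_fc"] > 0):
                        ok = False
                        break
                    worst_p = max(worst_p, float(row["padj"]))
                if not ok:
                    break
            if ok:
                worst[g] = worst_p
        qualifies[c] = worst

    seen: dict[str, int] = {}
    for q in qualifies.values():
        for g in q:
            seen[g] = seen.get(g, 0) + 1
    multi = {g for g, k in seen.items() if k > 1}
    out = {}
    for c in compartments:
        ranked = sorted(
            ((p, g) for g, p in qualifies[c].items() if g not in multi)
        )
        if len(ranked) < top_n:
            warnings.warn(f"{c}: only {len(ranked)} exclusive markers (< {top_n})")
        out[c] = GeneSignature(
            name=c,
            genes=[g for _, g in ranked[:top_n]],
            provenance=pd.DataFrame(ranked[:top_n], columns=["worst_padj", "gene"]).set_index("gene"),
        )
    return out
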