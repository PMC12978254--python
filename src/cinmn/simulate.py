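"""Synthetic data generators with known ground truth.

Every input the analysis modules consume can be generated here: multiplexed-IF
style segmented-cell and focus tables with spatially clustered micronuclei
(MN), isogenic clone/batch RNA-seq counts whose log-expression scales linearly
with MN burden, 2x2 genotype-by-treatment knockout experiments with a
cGAS-dependent induced gene subset, binned single-cell karyotypes with
controlled mis-segregation, and patient cohorts whose hazard depends on a CIN
score and myeloid:lymphoid skew.  Each generator returns its inputs together
with a :class:`SimTruth` holding the exact parameters needed to check
downstream recovery without re-simulation.

All randomness flows from a single integer seed per call; there is no hidden
global RNG state, and repeated calls with the same seed are bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueSimConfig",
    "ExpressionSimConfig",
    "SimTruth",
    "make_tissue",
    "make_isogenic_counts",
    "make_ko_experiment",
    "make_karyotypes",
    "make_cohort",
]


class SimTruth:
    """Ground-truth record for a simulated dataset.

    A thin mapping (``truth["key"]``) with JSON (de)serialization; numpy
    arrays are stored as lists on write.
    """

    def __init__(self, **data):
        self.data = dict(data)

    def __getitem__(self, key):
        return self.data[key]

    def __contains__(self, key):
        return key in self.data

    def keys(self):
        return self.data.keys()

    def to_json(self, path):
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(self.data, fh, default=_default, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Tissue with MN hotspots
# ---------------------------------------------------------------------------

_DEFAULT_STROMAL_PROPORTIONS = {
    "T_cell": 0.35,
    "macrophage": 0.25,
    "neutrophil": 0.15,
    "dendritic": 0.10,
    "fibroblast": 0.15,
}


@dataclass
class TissueSimConfig:
    """Configuration for a simulated stained tissue section.

    MN-dense "hotspots" are discs of radius ``2 * hotspot_sigma`` around
    random centers; tumor cells inside a hotspot micronucleate at
    ``mn_rate_hotspot`` instead of ``mn_rate_background``, and stromal cell
    types are re-weighted by ``hotspot_multiplier`` inside.  The hard-disc
    membership gives the true per-type fold enrichment a closed form,
    ``FE(t) = m_t / sum_s p_s m_s``, recorded in the returned truth.

    ``frac_area_outliers`` of cGAS+ foci are drawn with areas outside the
    0.25-7.5 um^2 detection window, and dim / stromal decoys are added, so the
    scoring filters have something to reject.
    """

    n_tumor_cells: int = 3000
    n_stromal_cells: int = 2000
    field_size: tuple[float, float] = (1000.0, 1000.0)  # um x um
    n_hotspots: int = 3
    hotspot_sigma: float = 80.0  # um; hotspot disc radius = 2 sigma
    mn_rate_background: float = 0.02  # expected MN per tumor cell
    mn_rate_hotspot: float = 0.15
    cell_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STROMAL_PROPORTIONS)
    )
    hotspot_multiplier: Mapping[str, float] = field(default_factory=dict)
    frac_area_outliers: float = 0.15
    frac_artifact_cells: float = 0.02
    seed: int = 0

    def validate(self):
        if self.n_tumor_cells <= 0 or self.n_stromal_cells < 0:
            raise ValueError("need at least one tumor cell")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.mn_rate_background < 0 or self.mn_rate_hotspot < 0:
            raise ValueError("MN rates must be >= 0")
        props = np.array(list(self.cell_type_proportions.values()), float)
        if not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise ValueError("cell_type_proportions must sum to 1")
        for t, m in self.hotspot_multiplier.items():
            if m <= 0:
                raise ValueError(f"hotspot multiplier for {t!r} must be > 0")


def make_tissue(cfg: TissueSimConfig):
    """Simulate a segmented tissue section with MN hotspots.

    Returns ``(cells, foci, truth)`` where *cells* is a SegmentedCellTable
    (cell_id, x, y, compartment, cell_type, marker intensities, ``af``
    autofluorescence) and *foci* a FociCandidateTable (focus_id, x, y, area,
    intensity, compartment, plus a ``is_true_mn`` column mirrored in truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    W, H = cfg.field_size
    r_hot = 2.0 * cfg.hotspot_sigma

    lo = min(r_hot, W / 2)
    centers = np.column_stack(
        [rng.uniform(lo, W - lo, cfg.n_hotspots), rng.uniform(min(r_hot, H / 2), H - min(r_hot, H / 2), cfg.n_hotspots)]
    ) if cfg.n_hotspots > 0 else np.empty((0, 2))

    def inside(xy):
        if len(centers) == 0:
            return np.zeros(len(xy), bool)
        d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return (d2.min(axis=1) <= r_hot**2)

    n_art = int(round(cfg.frac_artifact_cells * (cfg.n_tumor_cells + cfg.n_stromal_cells)))
    n_total = cfg.n_tumor_cells + cfg.n_stromal_cells + n_art
    xy = np.column_stack([rng.uniform(0, W, n_total), rng.uniform(0, H, n_total)])
    in_hot = inside(xy)

    compartment = np.array(
        ["tumor"] * cfg.n_tumor_cells + ["stroma"] * cfg.n_stromal_cells + ["artifact"] * n_art
    )
    types = list(cfg.cell_type_proportions)
    p = np.array([cfg.cell_type_proportions[t] for t in types], float)
    m = np.array([cfg.hotspot_multiplier.get(t, 1.0) for t in types], float)
    p_in = p * m / (p * m).sum()

    cell_type = np.empty(n_total, object)
    cell_type[compartment == "tumor"] = "tumor"
    cell_type[compartment == "artifact"] = "artifact"
    strom = compartment == "stroma"
    s_in = strom & in_hot
    s_out = strom & ~in_hot
    cell_type[s_in] = rng.choice(types, s_in.sum(), p=p_in)
    cell_type[s_out] = rng.choice(types, s_out.sum(), p=p)

    # marker intensities scaled on autofluorescence, as in multiplexed IF
    af = rng.lognormal(np.log(5.0), 0.2, n_total)
    cgas_factor = np.where(compartment == "tumor", 3.0, 1.5)
    sting_factor = np.where(compartment == "tumor", 2.0, 1.2)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n_total)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "compartment": compartment,
            "cell_type": cell_type.astype(str),
            "cgas": af * cgas_factor * rng.lognormal(0, 0.15, n_total),
            "sting": af * sting_factor * rng.lognormal(0, 0.15, n_total),
            "af": af,
        }
    )

    # --- cGAS+ MN foci -----------------------------------------------------
    tum = compartment == "tumor"
    rates = np.where(in_hot[tum], cfg.mn_rate_hotspot, cfg.mn_rate_background)
    n_mn_per_cell = rng.poisson(rates)
    parent = np.repeat(np.where(tum)[0], n_mn_per_cell)
    n_mn = len(parent)

    def _areas(n):
        n_out = rng.binomial(n, cfg.frac_area_outliers)
        a_in = np.exp(rng.normal(np.log(1.2), 0.45, n - n_out))
        a_in = np.clip(a_in, 0.25, 7.5)
        small = rng.uniform(0.05, 0.2499, n_out // 2 + n_out % 2)
        big = rng.uniform(7.51, 20.0, n_out // 2)
        a = np.concatenate([a_in, small, big])
        return rng.permuted(a)

    mn_xy = xy[parent] + rng.normal(0, 3.0, (n_mn, 2))
    mn_area = _areas(n_mn)
    mn_int = rng.lognormal(np.log(40.0), 0.3, n_mn)

    # decoys: dim tumor foci and stromal foci, to exercise intensity /
    # compartment filtering downstream
    n_dim = rng.poisson(0.10 * max(n_mn, 1))
    dim_xy = np.column_stack([rng.uniform(0, W, n_dim), rng.uniform(0, H, n_dim)])
    n_str = rng.poisson(0.10 * max(n_mn, 1))
    str_xy = np.column_stack([rng.uniform(0, W, n_str), rng.uniform(0, H, n_str)])

    foci = pd.DataFrame(
        {
            "focus_id": [f"f{i:05d}" for i in range(n_mn + n_dim + n_str)],
            "x": np.concatenate([mn_xy[:, 0], dim_xy[:, 0], str_xy[:, 0]]),
            "y": np.concatenate([mn_xy[:, 1], dim_xy[:, 1], str_xy[:, 1]]),
            "area": np.concatenate([mn_area, _areas(n_dim), _areas(n_str)]),
            "intensity": np.concatenate(
                [mn_int, rng.lognormal(np.log(5.0), 0.4, n_dim), rng.lognormal(np.log(40.0), 0.3, n_str)]
            ),
            "compartment": ["tumor"] * (n_mn + n_dim) + ["stroma"] * n_str,
        }
    )
    is_true = np.zeros(len(foci), bool)
    is_true[:n_mn] = (mn_area >= 0.25) & (mn_area <= 7.5)
    foci["is_true_mn"] = is_true

    fe_true = {t: float(mi / (p * m).sum()) for t, mi in zip(types, m)}
    truth = SimTruth(
        kind="tissue",
        hotspot_centers=centers,
        hotspot_radius=r_hot,
        expected_enrichment=fe_true,
        cell_in_hotspot=in_hot,
        mn_rate_background=cfg.mn_rate_background,
        mn_rate_hotspot=cfg.mn_rate_hotspot,
        n_true_mn=int(is_true.sum()),
        intensity_threshold=20.0,
        seed=cfg.seed,
    )
    return cells, foci, truth


# ---------------------------------------------------------------------------
# Isogenic clone/batch expression scaling with MN burden
# ---------------------------------------------------------------------------

_DEFAULT_GENOTYPES = {
    # cGAS+ MN per 100 cells, spanning a near-stable to highly unstable range
    "Cas9": 2.0,
    "p53KO": 8.0,
    "p53p16DKO": 18.0,
    "p53KO_dnMCAK": 40.0,
}


@dataclass
class ExpressionSimConfig:
    """Isogenic clone/batch RNA-seq design with MN-scaled genes.

    ``frac_cin_genes`` of genes get a nonzero slope (log2 expression units per
    MN%) drawn N(0, slope_scale); clone and batch-in-clone intercepts and a
    residual are added on the log2 scale and counts drawn negative-binomial
    around size-factor-scaled means.
    """

    n_genes: int = 2000
    genotypes: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GENOTYPES))
    n_clones: int = 3
    n_batches: int = 3
    frac_cin_genes: float = 0.10
    slope_scale: float = 0.03  # sd of true slopes, log2 units per MN%
    clone_sd: float = 0.15
    batch_sd: float = 0.10
    resid_sd: float = 0.20
    nb_dispersion: float = 0.05
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    libsize_sd: float = 0.15
    seed: int = 0

    def validate(self):
        if not 0 <= self.frac_cin_genes <= 1:
            raise ValueError("frac_cin_genes must be in [0, 1]")
        if min(self.clone_sd, self.batch_sd, self.resid_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_clones < 2:
            warnings.warn("n_clones < 2: clone random effect unidentifiable")


def _nb(rng, mean, dispersion):
    """Gamma-Poisson draw with DESeq2-style dispersion (var = mu + a mu^2)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) / shape)
    return rng.poisson(lam)


def make_isogenic_counts(cfg: ExpressionSimConfig):
    """Simulate gene x sample counts whose log-mean scales with MN burden."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    genes = np.array([f"g{i:04d}" for i in range(G)])

    n_cin = int(round(cfg.frac_cin_genes * G))
    slope = np.zeros(G)
    cin_idx = rng.choice(G, n_cin, replace=False)
    slope[cin_idx] = rng.normal(0, cfg.slope_scale, n_cin)

    base = rng.uniform(*cfg.baseline_log2_range, G)

    rows = []
    for g, mn in cfg.genotypes.items():
        for c in range(cfg.n_clones):
            for b in range(cfg.n_batches):
                rows.append((f"{g}.cl{c+1}.b{b+1}", g, f"{g}.cl{c+1}", f"b{b+1}", mn))
    meta = pd.DataFrame(rows, columns=["sample", "genotype", "clone", "batch", "mn"]).set_index("sample")

    clones = meta["clone"].unique()
    clone_eff = {cl: rng.normal(0, cfg.clone_sd, G) for cl in clones}
    # batch effects nested in clone: independent replicate-prep shifts
    cb_eff = {
        (cl, b): rng.normal(0, cfg.batch_sd, G)
        for cl in clones
        for b in meta["batch"].unique()
    }

    sf = rng.lognormal(0, cfg.libsize_sd, len(meta))
    counts = np.empty((G, len(meta)), dtype=np.int64)
    for j, (s, row) in enumerate(meta.iterrows()):
        log2mu = (
            base
            + slope * row["mn"]
            + clone_eff[row["clone"]]
            + cb_eff[(row["clone"], row["batch"])]
            + rng.normal(0, cfg.resid_sd, G)
        )
        counts[:, j] = _nb(rng, sf[j] * 2.0**log2mu, cfg.nb_dispersion)

    counts = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = SimTruth(
        kind="isogenic",
        true_slope=slope,
        is_cin_gene=(slope != 0.0),
        genes=genes,
        genotype_mn=dict(cfg.genotypes),
        size_factors=sf,
        seed=cfg.seed,
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# 2x2 knockout experiment with cGAS-dependent induced genes
# ---------------------------------------------------------------------------

def make_ko_experiment(
    n_genes: int = 2000,
    induced_set: Sequence[int] | None = None,
    dependent_subset: Sequence[int] | None = None,
    lfc: float = 2.0,
    dependence_attenuation: float = 0.0,
    nb_dispersion: float = 0.05,
    n_batches: int = 3,
    seed: int = 0,
    baseline_log2_range: tuple[float, float] = (4.0, 10.0),
    batch_sd: float = 0.10,
    libsize_sd: float = 0.15,
):
    """Simulate the 4-condition (Cas9/cGAS_KO x DMSO/MPS1i) paired design.

    ``induced_set`` genes gain ``lfc`` (log2) under MPS1i in Cas9 cells; for
    the ``dependent_subset`` the induction is multiplied by
    ``dependence_attenuation`` in the knockout.  One sample per condition per
    batch, mirroring a three-replicate paired design.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    if induced_set is None:
        induced_set = np.arange(int(round(0.10 * n_genes)))
    induced_set = np.asarray(induced_set, int)
    if dependent_subset is None:
        dependent_subset = induced_set[: len(induced_set) // 2]
    dependent_subset = np.asarray(dependent_subset, int)
    if not np.isin(dependent_subset, induced_set).all():
        raise ValueError("dependent_subset must be a subset of induced_set")

    induced = np.zeros(n_genes, bool)
    induced[induced_set] = True
    dependent = np.zeros(n_genes, bool)
    dependent[dependent_subset] = True

    base = rng.uniform(*baseline_log2_range, n_genes)
    rows = []
    for b in range(1, n_batches + 1):
        for gt in ("Cas9", "cGAS_KO"):
            for tr in ("DMSO", "MPS1i"):
                rows.append((f"{gt}.{tr}.b{b}", gt, tr, f"b{b}"))
    meta = pd.DataFrame(rows, columns=["sample", "genotype", "treatment", "batch"]).set_index("sample")

    batch_eff = {b: rng.normal(0, batch_sd, n_genes) for b in meta["batch"].unique()}
    sf = rng.lognormal(0, libsize_sd, len(meta))
    counts = np.empty((n_genes, len(meta)), dtype=np.int64)
    for j, (s, row) in enumerate(meta.iterrows()):
        eff = np.zeros(n_genes)
        if row["treatment"] == "MPS1i":
            eff = np.where(induced, lfc, 0.0)
            if row["genotype"] == "cGAS_KO":
                eff = np.where(dependent, lfc * dependence_attenuation, eff)
        log2mu = base + batch_eff[row["batch"]] + eff
        counts[:, j] = _nb(rng, sf[j] * 2.0**log2mu, nb_dispersion)

    counts = pd.DataFrame(counts, index=genes, columns=meta.index)
    truly_dependent = dependent & (dependence_attenuation < 1.0) & induced
    truth = SimTruth(
        kind="ko",
        genes=genes,
        induced=induced,
        dependent=truly_dependent,
        lfc=lfc,
        dependence_attenuation=dependence_attenuation,
        seed=seed,
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# Binned single-cell karyotypes
# ---------------------------------------------------------------------------

def make_karyotypes(
    n_cells: int = 100,
    n_bins: int = 300,
    bin_sizes: np.ndarray | None = None,
    base_ploidy: int = 2,
    missegregation_rate: float = 0.3,
    seed: int = 0,
    segmental_rate: float | None = None,
    n_chromosomes: int = 22,
    reads_per_copy: float = 25.0,
    frac_low_coverage: float = 0.1,
):
    """Simulate cell x bin integer copy numbers with mis-segregation.

    Each cell starts at ``base_ploidy``; whole-chromosome gains/losses occur
    Poisson(``missegregation_rate``) per cell and segmental events at
    ``segmental_rate`` (default half the whole-chromosome rate).  Per-bin read
    counts are drawn so a ``frac_low_coverage`` fraction of cells fail the
    <10-reads-per-bin-per-copy library QC.
    """
    rng = np.random.default_rng(seed)
    if segmental_rate is None:
        segmental_rate = missegregation_rate / 2.0
    if bin_sizes is None:
        bin_sizes = np.round(rng.lognormal(np.log(1e6), 0.25, n_bins)).astype(np.int64)
    bin_sizes = np.asarray(bin_sizes, np.int64)
    n_bins = len(bin_sizes)

    # contiguous chromosome blocks of roughly equal bin count
    edges = np.linspace(0, n_bins, n_chromosomes + 1).astype(int)
    chrom = np.empty(n_bins, object)
    for k in range(n_chromosomes):
        chrom[edges[k]: edges[k + 1]] = f"chr{k+1}"
    chrom = chrom.astype(str)

    cn = np.full((n_cells, n_bins), base_ploidy, dtype=np.int64)
    chroms = [f"chr{k+1}" for k in range(n_chromosomes)]
    for i in range(n_cells):
        for _ in range(rng.poisson(missegregation_rate)):
            c = chroms[rng.integers(n_chromosomes)]
            cn[i, chrom == c] = np.maximum(cn[i, chrom == c] + rng.choice([-1, 1]), 0)
        for _ in range(rng.poisson(segmental_rate)):
            c = chroms[rng.integers(n_chromosomes)]
            idx = np.where(chrom == c)[0]
            if len(idx) < 2:
                continue
            a, b = sorted(rng.choice(len(idx), 2, replace=False))
            seg = idx[a: b + 1]
            cn[i, seg] = np.maximum(cn[i, seg] + rng.choice([-1, 1]), 0)

    low = rng.random(n_cells) < frac_low_coverage
    rpc = np.where(low, rng.uniform(2.0, 8.0, n_cells), rng.uniform(15.0, 40.0, n_cells))
    scale = bin_sizes / bin_sizes.mean()
    reads = rng.poisson(rpc[:, None] * cn * scale[None, :])

    cell_ids = np.array([f"cell{i:03d}" for i in range(n_cells)])
    truth = SimTruth(
        kind="karyotype",
        cn=cn,
        bin_sizes=bin_sizes,
        chrom=chrom,
        base_ploidy=base_ploidy,
        reads_per_copy=rpc,
        expected_keep=(~low),
        seed=seed,
    )
    matrix = {
        "cn": pd.DataFrame(cn, index=cell_ids, columns=[f"bin{j:04d}" for j in range(n_bins)]),
        "bin_sizes": bin_sizes,
        "chrom": chrom,
        "expected": np.full(n_bins, float(base_ploidy)),
        "reads": pd.DataFrame(reads, index=cell_ids, columns=[f"bin{j:04d}" for j in range(n_bins)]),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Patient cohort with CIN- and skew-dependent hazard
# ---------------------------------------------------------------------------

def make_cohort(
    n_tumors: int = 200,
    mn_distribution: tuple | Callable[[np.random.Generator, int], np.ndarray] = ("lognormal", np.log(3.0), 0.7),
    effect_mn_on_myeloid: tuple[float, float] = (0.005, 0.02),
    hazard_coefficients: Mapping[str, float] | None = None,
    censoring_rate: float = 0.3,
    seed: int = 0,
    frac_other_response: float = 0.1,
    baseline_median_months: float = 24.0,
    effect_mn_on_sting: tuple[float, float] = (0.0, -0.05),
):
    """Simulate a per-tumor cohort table.

    ``effect_mn_on_myeloid`` gives the (responder, nonresponder) slopes of
    myeloid fraction on MN score.  Survival times are exponential with
    log-hazard linear in the standardized CIN score and myeloid:lymphoid skew
    (``hazard_coefficients`` keys ``"cin"`` and ``"skew"``); censoring is an
    independent exponential calibrated to ``censoring_rate``.
    """
    rng = np.random.default_rng(seed)
    if hazard_coefficients is None:
        hazard_coefficients = {"cin": 0.5, "skew": 0.4}

    if callable(mn_distribution):
        mn = np.asarray(mn_distribution(rng, n_tumors), float)
    else:
        name, *args = mn_distribution
        mn = getattr(rng, name)(*args, n_tumors)

    resp = rng.choice(
        ["R", "NR", "other"],
        n_tumors,
        p=[(1 - frac_other_response) / 2, (1 - frac_other_response) / 2, frac_other_response],
    )
    slope = np.where(resp == "NR", effect_mn_on_myeloid[1], effect_mn_on_myeloid[0])
    myeloid = np.clip(0.15 + slope * mn + rng.normal(0, 0.05, n_tumors), 0.0, 1.0)
    lymphoid = np.clip(0.25 + rng.normal(0, 0.05, n_tumors), 0.0, 1.0)
    # compartment protein levels: STING with response-specific MN slopes
    # (unbounded scale, unlike the abundance fractions)
    slope_st = np.where(resp == "NR", effect_mn_on_sting[1], effect_mn_on_sting[0])
    sting_malignant = 2.0 + slope_st * mn + rng.normal(0, 0.5, n_tumors)
    cgas_malignant = 1.5 + 0.02 * mn + rng.normal(0, 0.5, n_tumors)

    def z(v):
        return (v - v.mean()) / v.std()

    cin_mn = z(np.log(mn)) + rng.normal(0, 0.3, n_tumors)
    skew = myeloid - lymphoid
    cin70 = 1.2 * cin_mn + rng.normal(0, 0.4, n_tumors)
    aneuploidy = 0.8 * cin_mn + rng.normal(0, 0.4, n_tumors)
    cgas_sting = 0.3 * cin_mn + rng.normal(0, 1.0, n_tumors)
    purity = rng.beta(5, 2, n_tumors)
    leukocyte = np.clip(rng.beta(2, 5, n_tumors) + 0.3 * myeloid, 0.0, 1.0)

    lam0 = np.log(2.0) / baseline_median_months
    lam = lam0 * np.exp(hazard_coefficients["cin"] * z(cin_mn) + hazard_coefficients["skew"] * z(skew))
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate > 0:
        # exponential censoring with matched marginal rate hits the target
        # censoring fraction approximately for moderate hazard spread
        lam_c = lam0 * censoring_rate / max(1.0 - censoring_rate, 1e-9)
        t_cens = rng.exponential(1.0 / lam_c, n_tumors)
    else:
        t_cens = np.full(n_tumors, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    table = pd.DataFrame(
        {
            "tumor_id": [f"t{i:03d}" for i in range(n_tumors)],
            "mn_score": mn,
            "myeloid_frac": myeloid,
            "lymphoid_frac": lymphoid,
            "response": resp,
            "sting_malignant": sting_malignant,
            "cgas_malignant": cgas_malignant,
            "time_months": time,
            "event": event,
            "cin_mn": cin_mn,
            "cin70": cin70,
            "aneuploidy": aneuploidy,
            "cgas_sting": cgas_sting,
            "purity": purity,
            "leukocyte_fraction": leukocyte,
            "skew": skew,
        }
    ).set_index("tumor_id")

    truth = SimTruth(
        kind="cohort",
        slope_r=effect_mn_on_myeloid[0],
        slope_nr=effect_mn_on_myeloid[1],
        slope_diff=effect_mn_on_myeloid[1] - effect_mn_on_myeloid[0],
        sting_slope_r=effect_mn_on_sting[0],
        sting_slope_nr=effect_mn_on_sting[1],
        sting_slope_diff=effect_mn_on_sting[1] - effect_mn_on_sting[0],
        hazard_coefficients=dict(hazard_coefficients),
        censoring_rate=censoring_rate,
        seed=seed,
    )
    return table, truth
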