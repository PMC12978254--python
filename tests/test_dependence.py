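"""NB differential expression and cGAS-dependence classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cinmn import dependence as dep
from cinmn.simulate import _nb, make_ko_experiment


def counts_frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestFilterGenes:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([1, 1, 1, 1, 1, 0, 0, 0], True),   # total 5, nonzero 5
            ([4, 0, 0, 0, 0, 0, 0, 0], False),  # total < 5
            ([5, 0, 0, 0, 0, 0, 0, 0], False),  # nonzero in 1 < 4
            ([2, 1, 1, 1, 0, 0, 0, 0], True),
        ],
    )
    def test_joint_total_and_breadth_filter(self, row, kept):
        counts = counts_frame([row, [10] * 8])
        out = dep.filter_genes(counts)
        assert ("g0" in out.index) is kept


class TestSizeFactors:
    def test_doubling_a_library_doubles_its_factor(self, rng):
        """Doubling one library doubles its size factor relative to the rest
        (the gene-wise geometric-mean reference shifts by a common constant),
        so the normalized matrix is unchanged."""
        base = counts_frame(rng.poisson(100, (200, 4)))
        doubled = base.copy()
        doubled["s0"] = doubled["s0"] * 2
        sf0 = dep.size_factors(base)
        sf1 = dep.size_factors(doubled)
        ratio = sf1 / sf0
        assert ratio["s0"] / ratio["s1"] == pytest.approx(2.0, rel=1e-9)
        # normalized matrices agree up to one global constant (the shifted
        # geometric-mean reference)
        norm_ratio = (doubled / sf1) / (base / sf0)
        assert np.allclose(norm_ratio.to_numpy(), norm_ratio.iloc[0, 0], rtol=1e-9)

    def test_scaling_one_sample_leaves_lfc_unchanged(self, rng):
        counts = counts_frame(_nb(rng, np.full((400, 6), 500.0), 0.05))
        meta = pd.DataFrame({"treatment": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        de0 = dep.differential_expression(counts, meta, "treatment", "A", "B")
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 3
        de1 = dep.differential_expression(scaled, meta, "treatment", "A", "B")
        assert np.abs(de1["log2_fc"] - de0["log2_fc"]).median() < 0.02


class TestDifferentialExpression:
    def test_identical_groups_give_zero_lfc_high_p(self):
        row = np.array([100, 200, 150, 100, 200, 150])
        counts = counts_frame(np.tile(row, (50, 1)))
        meta = pd.DataFrame({"treatment": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        de = dep.differential_expression(counts, meta, "treatment", "A", "B")
        assert np.allclose(de["log2_fc"], 0.0, atol=1e-6)
        assert (de["p"] > 0.9).all()

    def test_null_type_one_error_near_nominal(self, rng):
        """Equal NB means in both groups: p < 0.05 in ~5% of 5000 genes."""
        mu = rng.uniform(50, 2000, 5000)[:, None] * np.ones((1, 6))
        counts = counts_frame(_nb(rng, mu, 0.05))
        meta = pd.DataFrame({"treatment": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        de = dep.differential_expression(counts, meta, "treatment", "A", "B")
        assert 0.03 < (de["p"] < 0.05).mean() < 0.075

    def test_fourfold_induction_recovered(self, rng):
        G = 2000
        mu = np.full((G, 6), 300.0)
        induced = np.zeros(G, bool)
        induced[:200] = True
        mu[np.ix_(induced, [3, 4, 5])] *= 4
        counts = counts_frame(_nb(rng, mu, 0.02))
        meta = pd.DataFrame({"treatment": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        de = dep.differential_expression(counts, meta, "treatment", "A", "B")
        assert de.loc[induced, "log2_fc"].median() == pytest.approx(2.0, abs=0.1)

    def test_requires_two_replicates(self):
        counts = counts_frame(np.full((10, 3), 50))
        meta = pd.DataFrame({"treatment": ["A", "A", "B"]}, index=counts.columns)
        with pytest.raises(ValueError, match="replicates"):
            dep.differential_expression(counts, meta, "treatment", "A", "B")

    def test_against_pydeseq2_on_induced_genes(self, rng):
        """Independent cross-check: log2 FCs agree with DESeq2 (pydeseq2) on
        a small simulated induction experiment."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        G = 300
        mu = np.full((G, 6), 400.0)
        mu[:30, 3:] *= 4
        counts = counts_frame(_nb(rng, mu, 0.05))
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        de = dep.differential_expression(counts, meta, "condition", "A", "B")

        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            res = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            res.summary()
        ref = res.results_df["log2FoldChange"]
        diff = (de["log2_fc"] - ref.loc[de.index]).abs()
        assert diff.median() < 0.1
        # both calls agree on which genes are strongly induced
        mine = set(de.index[(de["padj"] <= 0.01) & (de["log2_fc"] > 1)])
        theirs = set(ref.index[(res.results_df["padj"] <= 0.01) & (ref > 1)])
        overlap = len(mine & theirs) / max(len(mine | theirs), 1)
        assert overlap > 0.8


class TestPerBatchLfc:
    def make_design(self, counts_cas9_dmso, counts_cas9_mps):
        genes = [f"g{i}" for i in range(len(counts_cas9_dmso))]
        cols, data = [], []
        for b in range(3):
            for gt in ("Cas9", "cGAS_KO"):
                for tr, vals in (("DMSO", counts_cas9_dmso), ("MPS1i", counts_cas9_mps)):
                    cols.append((f"{gt}.{tr}.b{b+1}", gt, tr, f"b{b+1}"))
                    data.append(np.asarray(vals))
        counts = pd.DataFrame(np.array(data).T, index=genes, columns=[c[0] for c in cols])
        meta = pd.DataFrame(
            [c[1:] for c in cols], index=[c[0] for c in cols],
            columns=["genotype", "treatment", "batch"],
        )
        return counts, meta

    def test_identical_counts_zero_lfc(self):
        counts, meta = self.make_design([100, 50], [100, 50])
        lfc = dep.per_batch_log2fc(counts, meta, "Cas9")
        assert np.allclose(lfc.to_numpy(), 0.0)

    def test_exact_doubling_near_one(self):
        """With unit size factors (a genome-wide doubling would otherwise be
        absorbed into the depth normalization) an exact 2x gives lfc 1 at
        large counts, the pseudocount being negligible."""
        counts, meta = self.make_design([10000, 40000], [20000, 80000])
        unit_sf = pd.Series(1.0, index=counts.columns)
        lfc = dep.per_batch_log2fc(counts, meta, "Cas9", sf=unit_sf)
        assert np.allclose(lfc.to_numpy(), 1.0, atol=0.01)

    def test_matches_hand_computed_ratios(self, rng):
        a = rng.poisson(200, 5)
        b = rng.poisson(200, 5)
        counts, meta = self.make_design(a, b)
        sf = dep.size_factors(counts)
        lfc = dep.per_batch_log2fc(counts, meta, "Cas9")
        col = "Cas9.MPS1i.b1"
        ref = "Cas9.DMSO.b1"
        hand = np.log2((b / sf[col] + 0.5) / (a / sf[ref] + 0.5))
        assert np.allclose(lfc["b1"], hand)


class TestPairedT:
    def test_three_pair_textbook_value(self):
        """Paired t on 3 printed pairs equals the closed form."""
        x = np.array([[2.1, 1.8, 2.4]])
        y = np.array([[0.3, 0.5, 0.1]])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 2)
        res = stats.ttest_rel(x, y, axis=1)
        assert res.statistic[0] == pytest.approx(t_hand)
        assert res.pvalue[0] == pytest.approx(p_hand)


class TestClassification:
    def make_inputs(self, padj, lfc, lfc_c, lfc_k):
        de = pd.DataFrame({"padj": [padj], "log2_fc": [lfc]}, index=["g0"])
        lc = pd.DataFrame([lfc_c], index=["g0"], columns=["b1", "b2", "b3"])
        lk = pd.DataFrame([lfc_k], index=["g0"], columns=["b1", "b2", "b3"])
        return de, lc, lk

    def test_identical_induction_is_independent_changed(self):
        de, lc, lk = self.make_inputs(1e-5, 2.0, [2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        out = dep.classify_cgas_dependence(de, lc, lk)
        assert out["class"].iloc[0] == "cGAS_independent_changed"

    def test_padj_above_cut_is_unchanged_regardless_of_t(self):
        de, lc, lk = self.make_inputs(0.02, 2.0, [2.0, 2.1, 1.9], [0.0, 0.1, -0.1])
        out = dep.classify_cgas_dependence(de, lc, lk)
        assert out["class"].iloc[0] == "unchanged"

    def test_attenuated_induction_called_dependent(self):
        de, lc, lk = self.make_inputs(1e-6, 2.0, [2.0, 2.1, 1.9], [0.1, 0.0, 0.2])
        out = dep.classify_cgas_dependence(de, lc, lk)
        assert out["class"].iloc[0] == "cGAS_dependent_induced"

    def test_suppressed_mirror_rule(self):
        de, lc, lk = self.make_inputs(1e-6, -2.0, [-2.0, -2.1, -1.9], [-0.1, 0.0, -0.2])
        out = dep.classify_cgas_dependence(de, lc, lk)
        assert out["class"].iloc[0] == "cGAS_dependent_suppressed"

    def test_recovery_on_simulated_ko_experiment(self):
        """With full attenuation and strong induction the dependent-induced
        set is recovered with the power the paired three-batch design
        affords, at near-zero false-positive rate."""
        counts, meta, truth = make_ko_experiment(
            n_genes=1500, lfc=2.0, dependence_attenuation=0.0,
            nb_dispersion=0.05, n_batches=3, seed=21,
        )
        counts = dep.filter_genes(counts)
        cas9 = meta.index[meta["genotype"] == "Cas9"]
        de = dep.differential_expression(counts[cas9], meta.loc[cas9],
                                         "treatment", "DMSO", "MPS1i")
        lc = dep.per_batch_log2fc(counts, meta, "Cas9")
        lk = dep.per_batch_log2fc(counts, meta, "cGAS_KO")
        calls = dep.classify_cgas_dependence(de, lc, lk)
        td = pd.Series(truth["dependent"], index=truth["genes"]).loc[counts.index]
        pred = calls["class"] == "cGAS_dependent_induced"
        sens = (pred & td).sum() / td.sum()
        fpr = (pred & ~td).sum() / (~td).sum()
        assert sens > 0.5  # limited by the df=2 paired t test
        assert fpr <= 0.01


class TestConsensus:
    def make_calls(self, genes):
        return pd.DataFrame(
            {"class": ["cGAS_dependent_induced"] * len(genes)}, index=genes
        )

    def test_disjoint_sets_empty(self):
        out = dep.consensus_hits(
            {"OE33": self.make_calls(["a", "b"]), "SKGT4": self.make_calls(["c"])}
        )
        assert out == set()

    def test_identical_sets_preserved(self):
        out = dep.consensus_hits(
            {"OE33": self.make_calls(["a", "b"]), "SKGT4": self.make_calls(["a", "b"])}
        )
        assert out == {"a", "b"}

    def test_two_simulated_lines_share_truth_subset(self):
        shared = None
        sets = {}
        for i, line in enumerate(["OE33", "SKGT4"]):
            counts, meta, truth = make_ko_experiment(
                n_genes=800, lfc=2.5, dependence_attenuation=0.0,
                nb_dispersion=0.02, seed=31 + i,
            )
            counts = dep.filter_genes(counts)
            cas9 = meta.index[meta["genotype"] == "Cas9"]
            de = dep.differential_expression(counts[cas9], meta.loc[cas9],
                                             "treatment", "DMSO", "MPS1i")
            calls = dep.classify_cgas_dependence(
                de,
                dep.per_batch_log2fc(counts, meta, "Cas9"),
                dep.per_batch_log2fc(counts, meta, "cGAS_KO"),
            )
            sets[line] = calls
            truth_dep = set(np.asarray(truth["genes"])[np.asarray(truth["dependent"])])
            shared = truth_dep if shared is None else (shared & truth_dep)
        consensus = dep.consensus_hits(sets)
        # consensus is dominated by genes dependent in both lines' truth
        assert len(consensus & shared) / max(len(consensus), 1) > 0.9
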