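"""Thresholds, the TSA/TAA cascade, and single-cell specificity scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from pepscan.prioritize import (
    STATUS_LOW_TUMOR,
    STATUS_OGTEX,
    STATUS_PROTEIN,
    STATUS_TAA,
    STATUS_TOLERANCE,
    STATUS_TSA,
    PrioritizeConfig,
    ThresholdTable,
    average_nonzero_rphm,
    cell_specificity,
    compute_thresholds,
    evaluate_specificity,
    median_centered_cv,
    prioritize,
)
from pepscan.simulate import synthetic_cohort


def matrices(peptides, tumor, nat, ogtex, mtec):
    def f(vals, prefix):
        arr = np.asarray(vals, dtype=float)
        return pd.DataFrame(
            arr, index=peptides,
            columns=[f"{prefix}{i}" for i in range(arr.shape[1])],
        )

    return f(tumor, "T"), f(nat, "N"), f(ogtex, "G"), f(mtec, "M")


def meta_for(peptides, mhc_class="I", length=9):
    return pd.DataFrame(
        {"mhc_class": mhc_class, "length": length},
        index=pd.Index(peptides, name="peptide"),
    )


class TestAverageNonzero:
    def test_examples(self):
        assert average_nonzero_rphm([0, 0, 4, 2]) == 3.0
        assert average_nonzero_rphm([0, 0, 0]) == 0.0

    def test_equals_definition_on_random_rows(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(0, 10, size=50) * (rng.random(50) > 0.5)
        pos = row[row > 0]
        assert average_nonzero_rphm(row) == pytest.approx(pos.sum() / pos.size)


class TestComputeThresholds:
    def test_linear_interpolation_quantile(self):
        peptides = [f"p{i}" for i in range(100)]
        normals = pd.DataFrame(
            {"s0": np.arange(1.0, 101.0)}, index=peptides
        )
        thr = compute_thresholds(normals, meta_for(peptides),
                                 min_group_size=10)
        assert thr[("I", 9)] == pytest.approx(1.99)

    def test_identical_and_zero_groups(self):
        peptides = [f"p{i}" for i in range(120)]
        normals = pd.DataFrame({"s0": [5.0] * 120}, index=peptides)
        thr = compute_thresholds(normals, meta_for(peptides))
        assert thr[("I", 9)] == 5.0
        zeros = pd.DataFrame({"s0": [0.0] * 120}, index=peptides)
        assert compute_thresholds(zeros, meta_for(peptides))[("I", 9)] == 0.0

    def test_small_group_falls_back_to_pooled_class(self):
        peptides = [f"p{i}" for i in range(110)]
        meta = meta_for(peptides)
        meta.loc[meta.index[:10], "length"] = 10  # tiny group
        normals = pd.DataFrame(
            {"s0": np.linspace(1, 100, 110)}, index=peptides
        )
        with pytest.warns(UserWarning, match="pooled"):
            thr = compute_thresholds(normals, meta)
        assert thr[("I", 10)] == pytest.approx(
            np.percentile(np.linspace(1, 100, 110), 1)
        )
        assert thr[("I", 9)] == pytest.approx(
            np.percentile(np.linspace(1, 100, 110)[10:], 1)
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(pd.DataFrame(), meta_for([]))

    def test_uniform_group_lands_near_two(self):
        # 1st percentile of Uniform(0, 200) averages is ~2
        rng = np.random.default_rng(42)
        peptides = [f"p{i}" for i in range(10_000)]
        normals = pd.DataFrame(
            {"s0": rng.uniform(0, 200, size=10_000)}, index=peptides
        )
        thr = compute_thresholds(normals, meta_for(peptides))
        assert 1.6 <= thr[("I", 9)] <= 2.4


class TestCascade:
    def run_one(self, tumor, nat, ogtex, mtec, thr=2.0, **cfg_kwargs):
        peptides = ["pep1"]
        t, n, g, m = matrices(peptides, [tumor], [nat], [ogtex], [mtec])
        table = ThresholdTable({("I", 9): thr})
        res = prioritize(t, n, g, m, table, meta_for(peptides),
                         PrioritizeConfig(**cfg_kwargs))
        return res.loc["pep1", "status"]

    def test_tsa_when_ogtex_silent(self):
        # 0/300 oGTEx above threshold 2, clean NAT/mTEC
        status = self.run_one([10.0], [0.0], [0.0] * 300, [0.0])
        assert status == STATUS_TSA

    def test_taa_when_rare_but_tumor_dominant(self):
        # 2/300 above: not < 0.1%, but tumor max exceeds oGTEx max
        ogtex = [0.0] * 298 + [5.0, 5.0]
        assert self.run_one([10.0], [0.0], ogtex, [0.0]) == STATUS_TAA

    def test_nat_expression_trumps_ogtex_silence(self):
        assert self.run_one([10.0], [9.0], [0.0] * 300, [0.0]) == \
            STATUS_TOLERANCE
        assert self.run_one([10.0], [0.0], [0.0] * 300, [9.0]) == \
            STATUS_TOLERANCE

    def test_low_tumor_and_recurrent_exclusions(self):
        assert self.run_one([1.0], [0.0], [0.0] * 300, [0.0]) == \
            STATUS_LOW_TUMOR
        ogtex = [5.0] * 10 + [0.0] * 290  # 10 > floor(1% of 300) = 3
        assert self.run_one([10.0], [0.0], ogtex, [0.0]) == STATUS_OGTEX

    def test_protein_evidence_list_final_override(self):
        status = self.run_one([10.0], [0.0], [0.0] * 300, [0.0],
                              exclude_peptides=frozenset({"pep1"}))
        assert status == STATUS_PROTEIN

    def test_order_invariance_and_monotonicity(self):
        tumor, nat, ogtex, mtec, meta, labels = synthetic_cohort(seed=3)
        thr = compute_thresholds(ogtex, meta)
        res = prioritize(tumor, nat, ogtex, mtec, thr, meta)
        perm = np.random.default_rng(0).permutation(len(tumor))
        res_p = prioritize(tumor.iloc[perm], nat.iloc[perm], ogtex.iloc[perm],
                           mtec.iloc[perm], thr, meta)
        assert (res_p["status"].sort_index() == res["status"].sort_index()).all()
        # raising oGTEx expression of a TSA can only demote it
        pep = res.index[res["status"] == STATUS_TSA][0]
        ogtex2 = ogtex.copy()
        ogtex2.loc[pep] = 500.0
        res2 = prioritize(tumor, nat, ogtex2, mtec, thr, meta)
        assert res2.loc[pep, "status"] not in (STATUS_TSA, STATUS_TAA)

    def test_missing_threshold_group_reported(self):
        peptides = ["pep1"]
        t, n, g, m = matrices(peptides, [[10.0]], [[0.0]], [[0.0]], [[0.0]])
        table = ThresholdTable({("II", 15): 2.0})
        with pytest.raises(KeyError, match=r"\('I', 9\)"):
            prioritize(t, n, g, m, table, meta_for(peptides))


class TestCohortRecovery:
    def test_planted_labels_recovered_exactly(self):
        tumor, nat, ogtex, mtec, meta, labels = synthetic_cohort(seed=1)
        thr = compute_thresholds(ogtex, meta)
        assert thr[("I", 9)] == pytest.approx(1.0)
        res = prioritize(tumor, nat, ogtex, mtec, thr, meta)
        assert (res["status"] == labels).all()

    def test_specificity_fractions(self):
        tumor, nat, ogtex, mtec, meta, labels = synthetic_cohort(seed=2)
        thr = compute_thresholds(ogtex, meta)
        pos = labels.isin([STATUS_TSA, STATUS_TAA])
        pick = lambda df, mask: df.loc[mask]
        retention, exclusion = evaluate_specificity(
            tuple(pick(m, pos) for m in (tumor, nat, ogtex, mtec)),
            tuple(pick(m, ~pos) for m in (tumor, nat, ogtex, mtec)),
            thr, meta.loc[pos], meta.loc[~pos],
        )
        assert retention == 1.0
        assert exclusion == 1.0

    def test_empty_positive_set_is_nan_with_warning(self):
        tumor, nat, ogtex, mtec, meta, labels = synthetic_cohort(seed=2)
        empty = tuple(m.iloc[:0] for m in (tumor, nat, ogtex, mtec))
        with pytest.warns(UserWarning):
            retention, _ = evaluate_specificity(
                empty,
                (tumor, nat, ogtex, mtec),
                compute_thresholds(ogtex, meta),
                meta.iloc[:0], meta,
            )
        assert math.isnan(retention)


class TestCellSpecificity:
    def test_mcv_examples(self):
        assert median_centered_cv([0.9, 0.1, 0.1, 0.1]) == pytest.approx(4.0)
        assert median_centered_cv([0.5, 0.5, 0.5]) == 0.0
        assert median_centered_cv([0.0, 0.0, 0.4]) == math.inf

    def test_type_specific_peptide_ranked_first(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(60)]
        types = pd.Series(["T"] * 20 + ["B"] * 20 + ["Epi"] * 20, index=cells)
        counts = pd.DataFrame(0, index=["specific", "uniform", "rare"],
                              columns=cells)
        counts.loc["specific", types == "Epi"] = 5  # all epithelial cells
        counts.loc["uniform"] = 3  # everywhere
        counts.loc["rare", cells[:2]] = 1  # never above half of a type
        ranked = cell_specificity(counts, types, top_fraction=1.0)
        assert list(ranked["peptide"])[0] == "specific"
        assert "rare" not in set(ranked["peptide"])
        spec_mcv = ranked.set_index("peptide").loc["specific", "mcv"]
        assert spec_mcv == math.inf or spec_mcv > 1.0
        uni = ranked.set_index("peptide")
        assert "uniform" not in uni.index or uni.loc["uniform", "mcv"] == 0.0

    def test_below_half_everywhere_is_filtered(self):
        cells = [f"c{i}" for i in range(20)]
        types = pd.Series(["T"] * 10 + ["B"] * 10, index=cells)
        counts = pd.DataFrame(0, index=["p"], columns=cells)
        counts.loc["p", cells[:4]] = 1  # 40% of T cells, 0% of B
        assert cell_specificity(counts, types, top_fraction=1.0).empty

    def test_gene_level_takes_best_peptide(self):
        cells = [f"c{i}" for i in range(30)]
        types = pd.Series(["T"] * 10 + ["B"] * 10 + ["Epi"] * 10, index=cells)
        counts = pd.DataFrame(0, index=["p1", "p2"], columns=cells)
        counts.loc["p1", types == "T"] = 2
        counts.loc["p2"] = 1
        genes = {"p1": "G1", "p2": "G1"}
        ranked = cell_specificity(counts, types, peptide_genes=genes,
                                  top_fraction=1.0)
        assert len(ranked) == 1
        assert ranked.iloc[0]["peptide"] == "p1"

    def test_single_cell_type_rejected(self):
        cells = ["c1", "c2"]
        types = pd.Series(["T", "T"], index=cells)
        counts = pd.DataFrame(1, index=["p"], columns=cells)
        with pytest.raises(ValueError):
            cell_specificity(counts, types)
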