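"""Normalization, the stand-in DE test, gene-set logic and plate arithmetic."""

import numpy as np
import pandas as pd
import pytest

from epigerm.expression import (
    call_degs,
    classify_de,
    derive_pgc_genes,
    luciferase_normalize,
    marker_set_proportions,
    nearest_gene_activation,
    normalize_counts,
    stratified_expression,
    zscore_rows,
)
from epigerm.genomics import GeneModel, GenomicInterval


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.integers(0, 500, size=(20, 6)),
                       index=[f"g{i}" for i in range(20)],
                       columns=[f"s{i}" for i in range(6)])
    return mat


class TestNormalization:
    def test_per1e8_column_sums(self, toy_counts):
        norm = normalize_counts(toy_counts, "per1e8")
        assert np.allclose(norm.sum(axis=0), 1e8, rtol=1e-12)

    def test_rpkm_formula(self):
        mat = pd.DataFrame({"s1": [10]}, index=["g"])
        lengths = pd.Series({"g": 2000})
        lib = pd.Series({"s1": 1e6})
        out = normalize_counts(mat, "rpkm", lengths=lengths, library_sizes=lib)
        assert out.loc["g", "s1"] == pytest.approx(5.0)

    def test_zero_feature_stays_zero(self, toy_counts):
        toy_counts.loc["g0"] = 0
        for mode in ("per1e8", "cpm"):
            assert (normalize_counts(toy_counts, mode).loc["g0"] == 0).all()

    def test_zero_library_errors(self):
        mat = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="library"):
            normalize_counts(mat, "per1e8")


class TestDifferentialCalling:
    def test_strict_thresholds_at_boundaries(self):
        assert classify_de(np.log2(2.0), 0.0) == "NS"      # FC exactly 2
        assert classify_de(1.5, 0.05) == "NS"              # FDR exactly 0.05
        assert classify_de(1.01, 0.049) == "up"
        assert classify_de(-1.01, 0.049) == "down"

    def test_identical_groups_are_ns(self):
        mat = pd.DataFrame({
            "c1": [100, 50], "c2": [110, 55], "c3": [105, 52],
            "e1": [100, 50], "e2": [110, 55], "e3": [105, 52],
        }, index=["a", "b"])
        de = call_degs(mat, ["c1", "c2", "c3"], ["e1", "e2", "e3"])
        assert (de["status"] == "NS").all()
        assert np.allclose(de["log2fc"], 0.0)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.integers(10, 1000, size=(30, 6)),
                           index=[f"g{i}" for i in range(30)],
                           columns=list("abcdef"))
        lib = pd.Series(1e6, index=list("abcdef"))
        fwd = call_degs(mat, ["a", "b", "c"], ["d", "e", "f"], library_sizes=lib)
        rev = call_degs(mat, ["d", "e", "f"], ["a", "b", "c"], library_sizes=lib)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        swap = {"up": "down", "down": "up", "NS": "NS"}
        assert list(fwd["status"].map(swap)) == list(rev["status"])

    def test_noiseless_fc_two_is_ns(self):
        # one gene at exactly 2x against a large constant backdrop
        base = {f"g{i}": 10_000 for i in range(10)}
        ctrl = pd.Series({**base, "t": 100})
        exp = pd.Series({**base, "t": 200})
        mat = pd.DataFrame({"c1": ctrl, "c2": ctrl, "e1": exp, "e2": exp})
        lib = pd.Series(1e6, index=["c1", "c2", "e1", "e2"])
        de = call_degs(mat, ["c1", "c2"], ["e1", "e2"], library_sizes=lib)
        assert de.loc["t", "status"] == "NS"  # "greater than 2" is strict

    def test_fdr_control_under_full_null(self):
        rng = np.random.default_rng(8)
        r = 1 / 0.05
        mu = 200
        mat = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(2000, 6)),
            index=[f"g{i}" for i in range(2000)], columns=list("abcdef"))
        de = call_degs(mat, ["a", "b", "c"], ["d", "e", "f"])
        assert (de["fdr"] < 0.05).mean() <= 0.05


class TestGeneSets:
    @staticmethod
    def _de(passing, all_ids):
        return pd.DataFrame({
            "log2fc": [2.0 if g in passing else 0.0 for g in all_ids],
            "fdr": [0.01 if g in passing else 0.5 for g in all_ids],
        }, index=all_ids)

    def test_pgc_gene_set_logic_on_truth_table(self):
        ids = list("abcdef")
        # a: both weeks via soma; b: wk7 only; c: both via mixed routes;
        # d: wk9 only; e: neither; f: both via ES
        wk7_soma = self._de({"a", "b", "c"}, ids)
        wk7_es = self._de({"f"}, ids)
        wk9_soma = self._de({"a", "d"}, ids)
        wk9_es = self._de({"c", "f"}, ids)
        out = derive_pgc_genes(wk7_soma, wk7_es, wk9_soma, wk9_es)
        assert out["shared"] == {"a", "c", "f"}
        assert out["wk7_only"] == {"b"}
        assert out["wk9_only"] == {"d"}

    def test_intersection_mode_is_stricter(self):
        ids = list("ab")
        out = derive_pgc_genes(self._de({"a"}, ids), self._de({"b"}, ids),
                               self._de({"a"}, ids), self._de({"a"}, ids),
                               mode="intersection")
        assert out["shared"] == set()

    def test_marker_proportions_match_published_arithmetic(self):
        markers = {
            "migratory": {f"mig{i}" for i in range(142)},
            "mitotic": {f"mit{i}" for i in range(288)},
            "mitotic_arrest": {f"ma{i}" for i in range(937)},
        }
        flagged = ({f"mig{i}" for i in range(26)} | {f"mit{i}" for i in range(47)}
                   | {f"ma{i}" for i in range(310)})
        out = marker_set_proportions(flagged, markers)
        assert out.loc["migratory", "percent"] == 18
        assert out.loc["mitotic", "percent"] == 16
        assert out.loc["mitotic_arrest", "percent"] == 33

    def test_zero_flagged_is_zero_percent(self):
        out = marker_set_proportions(set(), {"m": {"a", "b"}})
        assert out.loc["m", "percent"] == 0

    def test_empty_marker_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            marker_set_proportions({"a"}, {"m": set()})


class TestStratification:
    def test_single_stratum_equals_global_summary(self):
        fc = pd.Series({"a": 1.0, "b": 3.0, "c": 5.0})
        out = stratified_expression({"all": ["a", "b", "c"]}, fc)
        assert out.loc["all", "n"] == 3
        assert out.loc["all", "mean"] == pytest.approx(3.0)
        assert out.loc["all", "median"] == pytest.approx(3.0)

    def test_empty_stratum_reported_not_dropped(self):
        fc = pd.Series({"a": 1.0})
        out = stratified_expression({"x": ["a"], "none": []}, fc)
        assert out.loc["none", "n"] == 0
        assert np.isnan(out.loc["none", "mean"])

    def test_overlapping_strata_rejected(self):
        fc = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="overlap"):
            stratified_expression({"x": ["a"], "y": ["a", "b"]}, fc)


class TestRepeatActivation:
    def test_nearest_genes_deduplicated_and_manual(self):
        genes = [
            GeneModel("g1", "g1", GenomicInterval("chr1", 1_000, 5_000, "+"), "+"),
            GeneModel("g2", "g2", GenomicInterval("chr1", 50_000, 60_000, "+"), "+"),
        ]
        inst = [GenomicInterval("chr1", 1_900, 2_100),   # nearest g1
                GenomicInterval("chr1", 3_000, 3_200),   # nearest g1 again
                GenomicInterval("chr1", 49_000, 49_100)]  # nearest g2
        fc = pd.Series({"g1": 2.0, "g2": -1.0})
        gene_set, dist = nearest_gene_activation(inst, genes, fc)
        assert gene_set == {"g1", "g2"}
        assert len(dist) == 2

    def test_gene_free_chromosome_excluded(self):
        genes = [GeneModel("g1", "g1", GenomicInterval("chr1", 0, 100, "+"), "+")]
        inst = [GenomicInterval("chr9", 0, 50)]
        gene_set, dist = nearest_gene_activation(inst, genes, pd.Series({"g1": 1.0}))
        assert gene_set == set()
        assert len(dist) == 0


class TestLuciferase:
    def test_relative_to_negative_control(self):
        ff = pd.Series({"neg": 5.0, "s": 20.0})
        gfp = pd.Series({"neg": 10.0, "s": 10.0})
        out = luciferase_normalize(ff, gfp, ["neg"])
        assert out["s"] == pytest.approx(4.0)
        assert out["neg"] == pytest.approx(1.0)

    def test_two_negative_wells_average(self):
        ff = pd.Series({"n1": 0.4, "n2": 0.6, "s": 1.0})
        gfp = pd.Series({"n1": 1.0, "n2": 1.0, "s": 1.0})
        out = luciferase_normalize(ff, gfp, ["n1", "n2"])
        assert out["s"] == pytest.approx(2.0)

    def test_nonpositive_gfp_errors(self):
        with pytest.raises(ValueError, match="GFP"):
            luciferase_normalize(pd.Series({"a": 1.0}), pd.Series({"a": 0.0}), ["a"])


class TestZscore:
    def test_closed_form_row(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        z, flagged = zscore_rows(mat)
        assert np.allclose(z.loc["r"], [-1.224744871, 0.0, 1.224744871])
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        mat = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        z, flagged = zscore_rows(mat)
        assert flagged == ["c"]
        assert (z.loc["c"] == 0).all()
        assert abs(z.loc["v"].mean()) < 1e-12
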