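"""Wright's F_ST estimators, summaries, selection and sharing fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from varstrat.afreq import allele_frequencies
from varstrat.fst import (
    fst_components,
    fst_site,
    fst_table,
    mean_fst,
    select_stratified,
    sharing_fraction,
)
from varstrat.simulate import CohortSpec, simulate_genotypes
from varstrat.types import GenotypeMatrix, VariantRecord

afs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestFstSite:
    def test_no_differentiation(self):
        assert fst_site(0.5, 100, 0.5, 100, "nei_gst") == pytest.approx(0.0)

    def test_fixed_difference(self):
        assert fst_site(1.0, 100, 0.0, 100, "nei_gst") == pytest.approx(1.0)
        assert fst_site(1.0, 100, 0.0, 100, "hudson") == pytest.approx(1.0)

    def test_nei_hand_evaluation(self):
        # p=0.2 vs 0.8: H_T = 0.5, H_S = 0.32 -> (0.5-0.32)/0.5 = 0.36
        assert fst_site(0.2, 50, 0.8, 50, "nei_gst") == pytest.approx(0.36)

    def test_monomorphic_both_same_allele_undefined(self):
        for est in ("hudson", "nei_gst"):
            out = fst_components([0.0], [10], [0.0], [10], est)
            assert not out["defined"][0]
            out = fst_components([1.0], [10], [1.0], [10], est)
            assert not out["defined"][0]

    def test_hudson_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            fst_site(0.5, 1, 0.5, 10, "hudson")

    @settings(derandomize=True, max_examples=150)
    @given(afs, afs, st.integers(2, 500), st.integers(2, 500))
    def test_symmetry_both_estimators(self, p1, p2, n1, n2):
        for est in ("hudson", "nei_gst"):
            a = fst_components([p1], [n1], [p2], [n2], est)
            b = fst_components([p2], [n2], [p1], [n1], est)
            if a["defined"][0]:
                assert a["fst_raw"][0] == pytest.approx(b["fst_raw"][0], abs=1e-12)

    def test_monotone_in_divergence_at_fixed_mean(self):
        # fixed pbar = 0.5, growing |p1 - p2|
        deltas = np.linspace(0.0, 0.49, 25)
        nei = [fst_site(0.5 - d, 200, 0.5 + d, 200, "nei_gst") for d in deltas]
        hud = [fst_site(0.5 - d, 200, 0.5 + d, 200, "hudson") for d in deltas]
        assert all(a < b for a, b in zip(nei, nei[1:]))
        assert all(a < b for a, b in zip(hud, hud[1:]))

    def test_nei_matches_brute_force_from_genotype_counts(self):
        # toy matrices: recompute H_T, H_S from raw genotype counts
        calls1 = np.array([[0], [1], [2], [1]], dtype=np.int8)
        calls2 = np.array([[2], [2], [1], [2]], dtype=np.int8)
        variants = [VariantRecord("1", 1, "A", "G")]
        gm = GenotypeMatrix(["a", "b", "c", "d", "e", "f", "g", "h"], variants,
                            np.vstack([calls1, calls2]),
                            ["p1"] * 4 + ["p2"] * 4)
        freqs = allele_frequencies(gm)
        p1 = freqs.for_pop("p1")["af"][0]
        p2 = freqs.for_pop("p2")["af"][0]
        pbar = (p1 + p2) / 2
        expected = (2 * pbar * (1 - pbar)
                    - (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2) / (2 * pbar * (1 - pbar))
        table = fst_table(freqs, "p1", "p2", "nei_gst")
        assert table["fst_raw"][0] == pytest.approx(expected)


class TestMeanFst:
    def test_singleton_mean_is_that_site(self):
        spec_rows = pd.DataFrame({
            "variant_id": ["v1"], "chrom": ["1"], "pos": [1], "ref": ["A"],
            "alt": ["G"], "af1": [0.2], "af2": [0.8], "n1": [50], "n2": [50],
            "fst": [0.36], "fst_raw": [0.36], "num": [0.18], "den": [0.5],
            "defined": [True], "present_both": [True], "estimator": ["nei_gst"]})
        out = mean_fst(spec_rows)
        assert out["mean"] == pytest.approx(0.36)
        assert out["n_sites"] == 1

    def test_all_zero_sites(self):
        table = pd.DataFrame({
            "variant_id": ["a", "b"], "chrom": ["1", "1"], "pos": [1, 2],
            "ref": ["A", "A"], "alt": ["G", "G"], "af1": [0.5, 0.3],
            "af2": [0.5, 0.3], "n1": [50, 50], "n2": [50, 50],
            "fst": [0.0, 0.0], "fst_raw": [0.0, 0.0], "num": [0.0, 0.0],
            "den": [0.5, 0.42], "defined": [True, True],
            "present_both": [True, True], "estimator": ["nei_gst"] * 2})
        assert mean_fst(table)["mean"] == 0.0

    def test_empty_table_errors(self):
        empty = pd.DataFrame({"defined": pd.Series([], dtype=bool),
                              "present_both": pd.Series([], dtype=bool),
                              "fst": pd.Series([], dtype=float),
                              "fst_raw": pd.Series([], dtype=float),
                              "num": pd.Series([], dtype=float),
                              "den": pd.Series([], dtype=float)})
        with pytest.raises(ValueError):
            mean_fst(empty)

    def test_hudson_null_unbiased_and_below_nei(self):
        # equal sampling, F -> 0: hudson mean ~ 0; nei shows positive
        # finite-sample bias
        spec = CohortSpec(n_samples=(50, 50), n_variants=8000,
                          drift_f=(1e-9, 1e-9), rng_seed=13)
        truth = simulate_genotypes(spec)
        freqs = allele_frequencies(truth.genotypes)
        hud = mean_fst(fst_table(freqs, "SA", "EUR", "hudson"))
        nei = mean_fst(fst_table(freqs, "SA", "EUR", "nei_gst"))
        assert abs(hud["ratio_of_averages"]) < 0.003
        assert hud["mean"] < nei["mean"]


class TestSelectStratified:
    def test_direct_filter(self):
        table = pd.DataFrame({
            "variant_id": ["A", "B", "C"], "chrom": ["1"] * 3, "pos": [1, 2, 3],
            "fst": [0.05, 0.15, 0.30], "fst_raw": [0.05, 0.15, 0.30],
            "defined": [True] * 3})
        out = select_stratified(table, 0.10)
        assert set(out["variant_id"]) == {"B", "C"}

    def test_threshold_one_empty_after_clipping(self):
        table = pd.DataFrame({"variant_id": ["A"], "chrom": ["1"], "pos": [1],
                              "fst": [1.0], "fst_raw": [1.2], "defined": [True]})
        assert len(select_stratified(table, 1.0)) == 0

    def test_threshold_zero_rejected_but_tiny_accepts_any_differentiation(self):
        table = pd.DataFrame({"variant_id": ["A"], "chrom": ["1"], "pos": [1],
                              "fst": [0.01], "fst_raw": [0.01], "defined": [True]})
        with pytest.raises(ValueError):
            select_stratified(table, 0.0)
        assert len(select_stratified(table, 1e-6)) == 1


class TestSharingFraction:
    def _freqs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])

    def test_superset_panel_all_shared(self):
        src = self._freqs([("1", i, "A", "G", 0.2) for i in range(1, 11)])
        out = sharing_fraction(src, src)
        assert out.set_index("af_class").loc["common", "fraction_shared"] == 1.0

    def test_disjoint_panel_none_shared(self):
        src = self._freqs([("1", 1, "A", "G", 0.2)])
        panel = self._freqs([("2", 1, "A", "G", 0.2)])
        out = sharing_fraction(src, panel)
        assert out.set_index("af_class").loc["common", "fraction_shared"] == 0.0

    def test_direct_count_per_bin(self):
        src = self._freqs([("1", i, "A", "G", 0.2) for i in range(1, 11)])
        panel = self._freqs([("1", i, "A", "G", 0.5) for i in range(1, 10)])
        out = sharing_fraction(src, panel).set_index("af_class")
        assert out.loc["common", "fraction_shared"] == pytest.approx(0.9)
        assert np.isnan(out.loc["rare", "fraction_shared"])  # empty bin reported

    def test_zero_panel_frequency_not_shared(self):
        src = self._freqs([("1", 1, "A", "G", 0.2)])
        panel = self._freqs([("1", 1, "A", "G", 0.0)])
        out = sharing_fraction(src, panel).set_index("af_class")
        assert out.loc["common", "fraction_shared"] == 0.0


class TestParameterRecovery:
    def test_fst_scan_recovers_generating_drift(self):
        # smaller-scale companion to the full recovery check: one F value
        spec = CohortSpec(n_samples=(100, 100), n_variants=10_000,
                          drift_f=(0.04, 0.04), rng_seed=21)
        truth = simulate_genotypes(spec)
        freqs = allele_frequencies(truth.genotypes)
        est = mean_fst(fst_table(freqs, "SA", "EUR", "hudson"))["ratio_of_averages"]
        assert est == pytest.approx(0.04, rel=0.10)
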