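"""SNP-strata tests: genotype calling, consistency, chi-square oracle, controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zwstrata.simulate import HET, HOM_ALT, HOM_REF, MISSING, NO_CALL, SimConfig
from zwstrata.strata import (VariantTable, call_genotype, call_genotypes,
                             classify_site, classify_sites, cross_validate_dna,
                             filter_sites, from_dataframe, proportion_chisq,
                             reverse_control, summarize_scaffolds)


class TestGenotypeCalling:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (50, 50, HET),          # minor 0.50 > 0.30
            (70, 30, NO_CALL),      # minor exactly 0.30: not exceeded
            (95, 5, HOM_REF),       # alt 0.05 <= 0.15
            (5, 95, HOM_ALT),
            (85, 15, HOM_REF),      # boundary 0.15 inclusive for homozygote
            (15, 85, HOM_ALT),
            (80, 20, NO_CALL),      # ambiguous band (0.15, 0.30]
            (65, 35, HET),
        ],
    )
    def test_allele_fraction_rules(self, ref, alt, expected):
        assert call_genotype(ref, alt) == expected

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError, match="zero total depth"):
            call_genotype(0, 0)

    def test_vectorized_calls_match_scalar(self, rng):
        ref = rng.integers(0, 60, size=(50, 3))
        alt = rng.integers(0, 60, size=(50, 3))
        meta = pd.DataFrame({"scaffold_id": ["s"] * 50, "pos": range(1, 51),
                             "ref": "A", "alt": "T", "qual": 50.0})
        sheet = pd.DataFrame({"sample": ["a", "b", "c"], "sex": ["female"] * 3,
                              "material": ["RNA_pool"] * 3})
        table = VariantTable(meta, ref, alt, ["a", "b", "c"], sheet)
        calls = call_genotypes(table, min_depth=10)
        for i in range(50):
            for j in range(3):
                total = ref[i, j] + alt[i, j]
                if total < 10:
                    assert calls[i, j] == MISSING
                else:
                    assert calls[i, j] == call_genotype(ref[i, j], alt[i, j])


class TestSiteFilters:
    def make_table(self, quals):
        n = len(quals)
        meta = pd.DataFrame({"scaffold_id": ["s"] * n, "pos": range(1, n + 1),
                             "ref": "A", "alt": "T", "qual": quals})
        depth = np.full((n, 1), 30)
        sheet = pd.DataFrame({"sample": ["x"], "sex": ["female"],
                              "material": ["RNA_pool"]})
        return VariantTable(meta, depth, depth.copy(), ["x"], sheet)

    def test_quality_boundary_is_strict(self):
        table = filter_sites(self.make_table([20.0, 20.01, 45.0]))
        assert list(table.meta["pos"]) == [2, 3]

    def test_shallow_observations_become_missing(self):
        meta = pd.DataFrame({"scaffold_id": ["s"], "pos": [1], "ref": ["A"],
                             "alt": ["T"], "qual": [50.0]})
        sheet = pd.DataFrame({"sample": ["x"], "sex": ["female"],
                              "material": ["RNA_pool"]})
        table = VariantTable(meta, np.array([[5]]), np.array([[4]]), ["x"], sheet)
        filtered = filter_sites(table, min_depth=10)
        assert call_genotypes(filtered)[0, 0] == MISSING

    def test_negative_depth_rejected(self):
        meta = pd.DataFrame({"scaffold_id": ["s"], "pos": [1], "ref": ["A"],
                             "alt": ["T"], "qual": [50.0]})
        sheet = pd.DataFrame({"sample": ["x"], "sex": ["female"],
                              "material": ["RNA_pool"]})
        with pytest.raises(ValueError, match="negative"):
            VariantTable(meta, np.array([[-1]]), np.array([[4]]), ["x"], sheet)


class TestClassifySite:
    def test_all_female_het_all_male_hom_is_zw_consistent(self):
        assert classify_site([HET] * 4, [HOM_REF] * 4) == "consistent"
        assert classify_site([HET] * 4, [HOM_ALT, HOM_REF, HOM_ALT, HOM_REF]) == "consistent"

    def test_all_het_is_other(self):
        assert classify_site([HET] * 4, [HET] * 4) == "other"

    def test_any_missing_pool_is_unassessable(self):
        assert classify_site([HET, HET, HET, MISSING], [HOM_REF] * 4) == "unassessable"
        assert classify_site([HET] * 4, [HOM_REF, NO_CALL, HOM_REF, HOM_REF]) == "unassessable"

    def test_wrong_pool_count_rejected(self):
        with pytest.raises(ValueError):
            classify_site([HET] * 3, [HOM_REF] * 4)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from([HOM_REF, HET, HOM_ALT, NO_CALL, MISSING]),
                    min_size=8, max_size=8))
    def test_polarity_symmetry(self, calls):
        """Swapping sex labels converts ZW-consistent into XY-consistent and
        leaves other/unassessable unchanged."""
        f, m = calls[:4], calls[4:]
        zw = classify_site(f, m, polarity="ZW")
        swapped_xy = classify_site(m, f, polarity="XY")
        assert zw == swapped_xy


class TestScaffoldSummary:
    def make_classes(self, spec):
        rows = []
        for scaf, (n_cons, n_other) in spec.items():
            for i in range(n_cons):
                rows.append((scaf, i + 1, "consistent"))
            for i in range(n_other):
                rows.append((scaf, 1000 + i, "other"))
        return pd.DataFrame(rows, columns=["scaffold_id", "pos", "site_class"])

    def assignments(self, scaffolds):
        return pd.DataFrame({"scaffold_id": scaffolds,
                             "class": ["autosome"] * len(scaffolds)})

    def test_twenty_percent_is_inclusive(self):
        classes = self.make_classes({"a": (2, 8)})  # 2/10 = 0.20 exactly
        summary = summarize_scaffolds(classes, self.assignments(["a"]))
        assert bool(summary["young_flag"].iloc[0])

    def test_minimum_snp_count_excludes_small_scaffolds(self):
        classes = self.make_classes({"a": (9, 0)})  # 9 SNPs, all consistent
        summary = summarize_scaffolds(classes, self.assignments(["a"]))
        assert not bool(summary["young_flag"].iloc[0])

    def test_no_consistent_sites_not_young(self):
        classes = self.make_classes({"a": (0, 100)})
        summary = summarize_scaffolds(classes, self.assignments(["a"]))
        assert not bool(summary["young_flag"].iloc[0])

    def test_non_autosomal_scaffolds_excluded(self):
        classes = self.make_classes({"z": (50, 0)})
        assignments = pd.DataFrame({"scaffold_id": ["z"], "class": ["Z"]})
        assert len(summarize_scaffolds(classes, assignments)) == 0

    def test_raising_min_prop_never_adds_scaffolds(self):
        classes = self.make_classes({"a": (2, 8), "b": (5, 5), "c": (9, 1)})
        assignments = self.assignments(["a", "b", "c"])
        previous = None
        for prop in (0.1, 0.2, 0.5, 0.9):
            flagged = set(
                summarize_scaffolds(classes, assignments, min_prop=prop)
                .query("young_flag")["scaffold_id"]
            )
            if previous is not None:
                assert flagged <= previous
            previous = flagged


class TestProportionChisq:
    def test_reproduces_published_enrichment(self):
        assert proportion_chisq(46, 110, 5165, 145204).chi2 == pytest.approx(454.4, abs=0.1)

    def test_reproduces_published_reverse_control(self):
        assert proportion_chisq(542, 1257, 30, 656).chi2 == pytest.approx(303.7, abs=0.1)

    def test_equal_proportions_give_zero(self):
        res = proportion_chisq(5, 10, 50, 100)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_group_order_invariance(self):
        a = proportion_chisq(46, 110, 5165, 145204)
        b = proportion_chisq(5165, 145204, 46, 110)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_chisq(11, 10, 1, 10)
        with pytest.raises(ValueError):
            proportion_chisq(1, 0, 1, 10)

    def test_matches_independent_implementation_on_random_tables(self, rng):
        """1,000 random 2x2 tables against scipy's Yates-corrected chi-square
        (the R prop.test convention), agreement to 1e-6."""
        from scipy.stats import chi2_contingency

        for _ in range(1000):
            n1, n2 = rng.integers(2, 500, size=2)
            k1, k2 = rng.integers(1, n1), rng.integers(1, n2)
            ours = proportion_chisq(int(k1), int(n1), int(k2), int(n2))
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            chi2, p, _, _ = chi2_contingency(table, correction=True)
            assert ours.chi2 == pytest.approx(chi2, abs=1e-6)
            assert ours.p_value == pytest.approx(p, abs=1e-6)


class TestReverseControl:
    def test_noise_free_genome_has_zero_xy_consistent_sites(self):
        from zwstrata.coverage import assign_coverage
        from zwstrata.simulate import (sample_sheet, simulate_coverage,
                                       simulate_genome, simulate_variants)

        cfg = SimConfig(seed=21, n_autosomal_scaffolds=0, n_z_scaffolds=0,
                        n_youngz_scaffolds=6, genotyping_error=0.0,
                        depth_dispersion=0.0, dna_missing_rate=0.0,
                        zw_fixed_fraction=1.0, n_transcripts=10)
        g = simulate_genome(cfg)
        table = from_dataframe(simulate_variants(g, cfg), sample_sheet(cfg))
        assigns, _ = assign_coverage(simulate_coverage(g, cfg))
        report = reverse_control(table, assigns)
        assert report["XY"]["n_consistent"] == 0
        assert report["XY"]["n_young_scaffolds"] == 0
        # young stratum fully recovered and DNA-confirmed at zero error
        truth = g.scaffolds.set_index("scaffold_id")["true_class"]
        young_true = set(truth.index[truth == "youngZ"])
        assert set(report["ZW"]["young_scaffolds"]) == young_true
        assert report["ZW"]["dna_proportion"] == pytest.approx(1.0)

    def test_sex_label_permutation_swaps_polarities(self):
        """Relabeling every female sample as male and vice versa turns the
        ZW analysis into the XY analysis exactly: under the symmetric null
        the two polarities are the same test on permuted labels."""
        from zwstrata.coverage import assign_coverage
        from zwstrata.simulate import (sample_sheet, simulate_coverage,
                                       simulate_genome, simulate_variants)
        from zwstrata.strata import run_polarity

        cfg = SimConfig(seed=22, n_autosomal_scaffolds=40, n_z_scaffolds=0,
                        n_youngz_scaffolds=4, genotyping_error=0.05,
                        n_transcripts=10)
        g = simulate_genome(cfg)
        variants = simulate_variants(g, cfg)
        sheet = sample_sheet(cfg)
        assigns, _ = assign_coverage(simulate_coverage(g, cfg))
        table = from_dataframe(variants, sheet)
        swapped_sheet = sheet.copy()
        swapped_sheet["sex"] = sheet["sex"].map({"female": "male", "male": "female"})
        swapped = from_dataframe(variants, swapped_sheet)
        zw_swapped = run_polarity(swapped, assigns, polarity="ZW")
        xy_original = run_polarity(table, assigns, polarity="XY")
        for key in ("n_sites", "n_consistent", "n_young_scaffolds",
                    "young_scaffolds", "dna_assessable", "dna_consistent"):
            assert zw_swapped[key] == xy_original[key], key


def test_cross_validation_counts(small_variants, pool_sheet):
    table = from_dataframe(small_variants, pool_sheet)
    mask = np.ones(len(table.meta), dtype=bool)
    n_a, n_c, prop = cross_validate_dna(table, mask)
    assert 0 <= n_c <= n_a <= len(table.meta)
    assert prop == pytest.approx(n_c / n_a)
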