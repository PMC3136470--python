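"""Qualification pipeline: filters, outlier mask, normalization, log2 ratios."""

import numpy as np
import pandas as pd
import pytest

from symbioquant import quant
from symbioquant.errors import ValidationError
from symbioquant.synthetic_data import SimulationConfig, gen_psm_dataset

from conftest import (
    brute_outlier_mask,
    brute_qualified_set,
    make_count_matrix,
    random_count_matrix,
    simple_catalog,
    swap_sites,
)


def full_presence_matrix(values_by_acc, uniq=5, n_replicates=4):
    """Matrix where each accession has the given per-(site, rep) values."""
    counts, uniqd = {}, {}
    for acc, sitevals in values_by_acc.items():
        for s, vals in sitevals.items():
            uniqd[(acc, s)] = uniq
            for r, v in enumerate(vals, start=1):
                counts[(acc, s, r)] = v
    return make_count_matrix(counts, uniqd, n_replicates=n_replicates)


class TestPresenceFilter:
    def test_partial_presence_retained_under_either_scope(self):
        counts = {("P1", "A", r): (1 if r <= 3 else 0) for r in range(1, 5)}
        counts.update({("P1", "B", r): 2 for r in range(1, 5)})
        m = make_count_matrix(counts, {("P1", "A"): 3, ("P1", "B"): 3})
        kept_either, _ = quant.filter_replicate_presence(m, "either")
        kept_both, excl_both = quant.filter_replicate_presence(m, "both")
        assert list(kept_either.accessions) == ["P1"]
        assert list(kept_both.accessions) == []
        assert excl_both == ["P1"]

    def test_full_presence_retained_under_every_scope(self):
        m = full_presence_matrix({"P1": {"A": [1, 1, 1, 1], "B": [1, 1, 1, 1]}})
        for scope in ("both", "either"):
            kept, excl = quant.filter_replicate_presence(m, scope)
            assert list(kept.accessions) == ["P1"] and excl == []

    def test_absent_everywhere_excluded(self):
        m = full_presence_matrix({"P1": {"A": [0, 0, 0, 0], "B": [0, 0, 0, 0]}})
        for scope in ("both", "either"):
            kept, excl = quant.filter_replicate_presence(m, scope)
            assert excl == ["P1"]

    def test_all_presence_patterns_match_scope_rule(self):
        """Enumerate every 2-replicate presence pattern against the rule."""
        for bits in range(16):
            vals = [(bits >> i) & 1 for i in range(4)]
            m = full_presence_matrix(
                {"P1": {"A": vals[:2], "B": vals[2:]}}, n_replicates=2
            )
            present_a, present_b = all(vals[:2]), all(vals[2:])
            for scope, expect in (
                ("both", present_a and present_b),
                ("either", present_a or present_b),
            ):
                kept, _ = quant.filter_replicate_presence(m, scope)
                assert (len(kept.accessions) == 1) == expect, (bits, scope)


class TestUniquePeptideFilter:
    @pytest.mark.parametrize(
        "uniq_a,uniq_b,kept", [(3, 1, True), (2, 2, False), (0, 3, True), (2, 1, False)]
    )
    def test_max_over_sites_meets_threshold(self, uniq_a, uniq_b, kept):
        counts = {("P1", s, r): 1 for s in "AB" for r in range(1, 5)}
        m = make_count_matrix(counts, {("P1", "A"): uniq_a, ("P1", "B"): uniq_b})
        retained, _ = quant.filter_unique_peptides(m, 3)
        assert (len(retained.accessions) == 1) == kept

    def test_random_matrix_matches_bruteforce(self, rng):
        m, counts, uniq, reps = random_count_matrix(rng)
        retained, _ = quant.filter_unique_peptides(m, 3)
        expected = {
            a
            for a in m.accessions
            if max(uniq[(a, "A")], uniq[(a, "B")]) >= 3
        }
        assert set(retained.accessions) == expected


class TestOutlierMask:
    def test_two_sd_rule_on_spiked_replicates(self):
        """Group stats make {10,11,9,300} NOT maskable at k=2 (max pop z is
        sqrt(3) for n=4); the same data masks the spike at k=1."""
        m = full_presence_matrix({"P1": {"A": [10, 11, 9, 300], "B": [5, 5, 5, 5]}})
        masked, _ = quant.mask_outliers(m, k=2.0)
        assert masked.mask.to_numpy().sum() == 0
        assert list(masked.mask.loc["P1", "A"]) == brute_outlier_mask([10, 11, 9, 300], 2.0)
        masked1, _ = quant.mask_outliers(m, k=1.0)
        assert list(masked1.mask.loc["P1", "A"]) == [False, False, False, True]
        assert list(masked1.mask.loc["P1", "A"]) == brute_outlier_mask([10, 11, 9, 300], 1.0)

    def test_constant_group_masks_nothing(self):
        m = full_presence_matrix({"P1": {"A": [5, 5, 5, 5], "B": [5, 5, 5, 5]}})
        masked, _ = quant.mask_outliers(m, 2.0)
        assert not masked.mask.any().any()

    def test_masking_is_idempotent(self, rng):
        m, *_ = random_count_matrix(rng)
        once, _ = quant.mask_outliers(m, 1.0)
        twice, _ = quant.mask_outliers(once, 1.0)
        pd.testing.assert_frame_equal(once.mask, twice.mask)

    def test_matches_bruteforce_per_group(self, rng):
        m, counts, _, reps = random_count_matrix(rng)
        masked, _ = quant.mask_outliers(m, 1.5)
        for acc in m.accessions:
            for site in ("A", "B"):
                vals = [counts[(acc, site, r)] for r in range(1, reps + 1)]
                assert list(masked.mask.loc[acc, site]) == brute_outlier_mask(vals, 1.5)

    def test_low_replicate_groups_flagged(self):
        # 8 replicates: a single huge value IS beyond 2 population SDs
        m = full_presence_matrix(
            {"P1": {"A": [10] * 7 + [1000], "B": [5] * 8}}, n_replicates=8
        )
        masked, flagged = quant.mask_outliers(m, 2.0)
        assert masked.mask.loc["P1", "A"].sum() == 1
        assert flagged == []


class TestNormalization:
    def test_factor_is_ratio_of_site_totals(self):
        m = full_presence_matrix({"P1": {"A": [50, 40, 30, 30], "B": [25, 25, 25, 25]}})
        norm, report = quant.normalize_total(m, "A")
        assert report.factor == pytest.approx(1.50)
        assert norm["B"].to_numpy().sum() == pytest.approx(150.0)

    def test_equal_totals_leave_matrix_unchanged(self):
        m = full_presence_matrix({"P1": {"A": [10, 10, 10, 10], "B": [10, 10, 10, 10]}})
        norm, report = quant.normalize_total(m, "A")
        assert report.factor == 1.0
        assert (norm.to_numpy() == m.counts.to_numpy()).all()

    def test_post_normalization_totals_agree(self, rng):
        for _ in range(5):
            m, *_ = random_count_matrix(rng)
            if m.counts["A"].to_numpy().sum() == 0 or m.counts["B"].to_numpy().sum() == 0:
                continue
            norm, report = quant.normalize_total(m, "A")
            assert norm["B"].to_numpy().sum() == pytest.approx(
                norm["A"].to_numpy().sum(), rel=1e-9
            )

    def test_zero_total_is_an_error(self):
        m = full_presence_matrix({"P1": {"A": [1, 1, 1, 1], "B": [0, 0, 0, 0]}})
        with pytest.raises(ValidationError):
            quant.normalize_total(m, "A")


class TestZeroFloorAndRatios:
    def test_floor_replaces_only_exact_zeros(self):
        out = quant.replace_zeros(np.array([0.0, 0.1, 2.0, 0.0]), 0.2)
        assert list(out) == [0.2, 0.1, 2.0, 0.2]

    def test_vector_of_zeros(self):
        assert list(quant.replace_zeros(np.zeros(4))) == [0.2] * 4

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            quant.replace_zeros(np.array([-1.0]))

    def test_log2_ratio_of_means(self):
        m = full_presence_matrix({"P1": {"A": [8, 8, 8, 8], "B": [2, 2, 2, 2]}})
        stats = quant.log2_ratios(
            m.counts.astype(float), m.mask, ("A", "B")
        )
        assert stats.at["P1", "log2_ratio"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        m = full_presence_matrix({"P1": {"A": [4, 4, 4, 4], "B": [4, 4, 4, 4]}})
        stats = quant.log2_ratios(m.counts.astype(float), m.mask, ("A", "B"))
        assert stats.at["P1", "log2_ratio"] == 0.0


class TestHousekeepingCheck:
    def _table(self, ratios):
        return pd.DataFrame(
            {
                "qualified": True,
                "log2_ratio": ratios,
            },
            index=pd.Index([f"H{i}" for i in range(len(ratios))], name="accession"),
        )

    def test_reports_mean_of_per_protein_ratios(self):
        table = self._table([0.5, 0.2, 0.3])
        catalog = simple_catalog(["H0", "H1", "H2"], housekeeping=("H0", "H1", "H2"))
        rep = quant.housekeeping_check(table, catalog)
        assert rep.mean == pytest.approx(1.0 / 3.0)
        assert list(rep.ratios) == [0.5, 0.2, 0.3]

    def test_zero_ratios_pass_any_tolerance(self):
        table = self._table([0.0, 0.0])
        catalog = simple_catalog(["H0", "H1"], housekeeping=("H0", "H1"))
        rep = quant.housekeeping_check(table, catalog, tol_mean=1e-12, tol_sd=1e-12)
        assert rep.verdict == "PASS"

    def test_no_housekeeping_is_indeterminate(self):
        table = self._table([0.1])
        catalog = simple_catalog(["H0"])  # not flagged housekeeping
        with pytest.warns(UserWarning):
            rep = quant.housekeeping_check(table, catalog)
        assert rep.verdict == "INDETERMINATE"

    def test_null_simulation_centers_near_zero(self):
        """Housekeeping (true FC 0, mean 50) log2 ratios average near 0."""
        means = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_proteins=60, expand_psms=False, low_peptide_fraction=0.0, seed=seed
            )
            ds = gen_psm_dataset(cfg)
            res = quant.qualify(ds.truth_count_matrix(), ds.catalog)
            hk = quant.housekeeping_check(res.table, ds.catalog)
            if not np.isnan(hk.mean):
                means.append(hk.mean)
        assert abs(np.mean(means)) < 0.2


class TestQualify:
    def test_qualified_set_matches_bruteforce_composition(self, rng):
        for _ in range(10):
            m, counts, uniq, reps = random_count_matrix(rng)
            for scope in ("both", "either"):
                res = quant.qualify(m, None, quant.QuantConfig(presence_scope=scope))
                # normalization can fail only if a site total is zero; the
                # random matrices always carry positive totals
                expected = brute_qualified_set(counts, uniq, reps, scope, 3, 2.0)
                got = set(res.table.index[res.table["qualified"]])
                assert got == expected

    def test_everything_qualifies_when_all_rules_met(self):
        m = full_presence_matrix(
            {
                "P1": {"A": [5, 6, 7, 8], "B": [5, 5, 5, 5]},
                "P2": {"A": [9, 9, 9, 9], "B": [1, 2, 1, 2]},
            }
        )
        res = quant.qualify(m)
        assert res.n_qualified == res.n_identified == 2

    def test_empty_matrix_reports_zero_over_zero(self):
        cols = pd.MultiIndex.from_tuples(
            [("A", 1), ("B", 1)], names=["site", "replicate"]
        )
        from symbioquant.psm_io import CountMatrix

        m = CountMatrix(
            pd.DataFrame(columns=cols, dtype=np.int64),
            pd.DataFrame(columns=["A", "B"], dtype=np.int64),
        )
        res = quant.qualify(m)
        assert res.n_identified == 0 and res.n_qualified == 0

    def test_exclusion_accounting_is_exact(self, rng):
        m, *_ = random_count_matrix(rng)
        res = quant.qualify(m)
        assert res.n_identified == res.n_qualified + sum(
            len(v) for v in res.exclusions.values()
        )
        reasons = res.table.loc[~res.table["qualified"], "reason"]
        assert set(reasons) <= {"missing_replicate", "too_few_unique_peptides"}

    def test_requalifying_qualified_subset_is_noop(self, rng):
        m, *_ = random_count_matrix(rng)
        res = quant.qualify(m)
        sub = m.subset(res.table.index[res.table["qualified"]])
        res2 = quant.qualify(sub)
        assert res2.n_qualified == res2.n_identified == res.n_qualified

    def test_scale_invariance_of_ratios(self, rng):
        base = full_presence_matrix(
            {
                f"P{i}": {
                    "A": list(rng.integers(5, 80, 4)),
                    "B": list(rng.integers(5, 80, 4)),
                }
                for i in range(20)
            }
        )
        ref = quant.qualify(base).table["log2_ratio"]
        for c in (0.1, 3, 17):
            from symbioquant.psm_io import CountMatrix

            scaled_counts = base.counts.astype(float).copy()
            for col in scaled_counts["B"].columns:
                scaled_counts[("B", col)] *= c
            scaled = CountMatrix(scaled_counts, base.unique_peptides)
            got = quant.qualify(scaled).table["log2_ratio"]
            assert np.max(np.abs(got.to_numpy() - ref.to_numpy())) < 1e-9

    def test_site_swap_negates_every_ratio(self, rng):
        m = full_presence_matrix(
            {
                f"P{i}": {
                    "A": list(rng.integers(5, 80, 4)),
                    "B": list(rng.integers(5, 80, 4)),
                }
                for i in range(15)
            }
        )
        fwd = quant.qualify(m).table["log2_ratio"]
        rev = quant.qualify(swap_sites(m), None, quant.QuantConfig(reference_site="B")).table[
            "log2_ratio"
        ]
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-9)

    def test_fold_change_recovery_on_clean_counts(self):
        """Noise-free limit: symmetric planted log2 FCs come back exactly."""
        planted = {"P1": 2.0, "P2": -2.0, "P3": 0.0, "P4": 0.0}
        counts = {}
        for acc, fc in planted.items():
            a = round(40.0 * 2 ** (fc / 2))
            b = round(40.0 * 2 ** (-fc / 2))
            for r in range(1, 5):
                counts[(acc, "A", r)] = a
                counts[(acc, "B", r)] = b
        m = make_count_matrix(counts, {(a, s): 5 for a in planted for s in "AB"})
        res = quant.qualify(m)
        assert res.normalization.factor == pytest.approx(1.0)
        got = res.table["log2_ratio"]
        for acc, fc in planted.items():
            assert got[acc] == pytest.approx(fc, abs=1e-12)
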