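"""qc: HWE exact test vs enumeration, filters, PI_HAT, sex inference."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln

from tgspipe.qc import (
    QCError,
    QCThresholds,
    filter_variants,
    genotype_counts,
    heterozygosity_outliers,
    hwe_exact_p,
    ld_prune,
    maf,
    pi_hat_exclusions,
    relatedness,
    run_sample_qc,
    sex_check,
)
from tgspipe.simulate import SimulationConfig, simulate_cohort, simulate_genotypes

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent HWE oracle: direct factorial enumeration of all tables with the
# observed allele counts, nothing shared with the recurrence implementation.
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    if min(nA, 2 * n - nA) == 0:
        return 1.0

    def log_prob(het):
        homA = (nA - het) // 2
        homa = n - het - homA
        if homA < 0 or homa < 0:
            return -math.inf
        return (
            gammaln(n + 1)
            - gammaln(homA + 1) - gammaln(het + 1) - gammaln(homa + 1)
            + het * math.log(2.0)
            + gammaln(nA + 1) + gammaln(2 * n - nA + 1) - gammaln(2 * n + 1)
        )

    hets = [h for h in range(min(nA, 2 * n - nA) + 1) if (h - nA) % 2 == 0]
    lps = {h: log_prob(h) for h in hets}
    obs = lps[n_Aa]
    total = sum(math.exp(v) for v in lps.values())
    p = sum(math.exp(v) for v in lps.values() if v <= obs + 1e-12) / total
    return min(p, 1.0)


class TestMAF:
    def test_arithmetic(self):
        assert maf([0, 1, 2, 2]) == pytest.approx(0.375)  # alt f = 0.625

    def test_monomorphic_both_directions(self):
        assert maf([0, 0, 0, 0]) == 0.0
        assert maf([2, 2, 2, 2]) == 0.0  # f = 1 folds to 0

    def test_all_missing_undefined(self):
        assert math.isnan(maf([np.nan, np.nan]))


class TestHWE:
    def test_single_table_is_one(self):
        assert hwe_exact_p(5, 0, 0) == 1.0

    def test_two_table_enumeration(self):
        # (1,0,1): allele counts 2/2, possible hets {0, 2};
        # P(het=0) = 1/3, P(het=2) = 2/3 -> observed het 0 has p = 1/3
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_p(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)

    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
    )
    def test_symmetric_in_homozygote_classes(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_p(a, h, b) == pytest.approx(hwe_exact_p(b, h, a), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(QCError):
            hwe_exact_p(-1, 0, 1)
        with pytest.raises(QCError):
            hwe_exact_p(0, 0, 0)


class TestFilterVariants:
    def _fixture(self):
        # 6 variants engineered to fail one filter each (or none):
        # v0 info 0.55 -> info; v1 30% missing -> missing; v2 all-het -> HWE;
        # v3 maf 0.025 -> maf; v4, v5 clean.
        n = 20
        col_info = [1.0] * n
        col_missing = [0.0] * 6 + [None] * 6 + [1.0] * 8
        col_hwe = [1.0] * n
        col_rare = [1.0] + [0.0] * (n - 1)
        clean1 = [0.0, 1.0, 2.0, 1.0] * 5
        clean2 = [1.0, 1.0, 0.0, 2.0, 0.0] * 4
        dosage = list(zip(col_info, col_missing, col_hwe, col_rare, clean1, clean2))
        return make_matrix(
            [list(r) for r in dosage],
            info=[0.55, 0.9, 0.9, 0.9, 0.9, 0.9],
        )

    def test_attribution_one_failure_per_filter(self):
        m = self._fixture()
        out, report = filter_variants(m, QCThresholds())
        assert out.rsids == ["rs4", "rs5"]
        stages = {e.item_id: e.stage for e in report.exclusions}
        assert stages == {"rs0": "info", "rs1": "missing", "rs2": "hwe", "rs3": "maf"}

    def test_boundary_values_retained(self):
        # MAF exactly 0.05 and missing rate exactly 0.02 survive (strict >/<)
        n = 100
        rare = [1.0] * 10 + [0.0] * 90  # alt f = 0.05
        # missing rate exactly 0.02; remaining genotypes kept HWE-consistent
        missing = [None] * 2 + ([0.0, 1.0, 1.0, 2.0] * 25)[:98]
        m = make_matrix([list(r) for r in zip(rare, missing)], info=[0.6, 0.6])
        out, report = filter_variants(m, QCThresholds())
        assert out.rsids == ["rs0", "rs1"]
        assert report.n_excluded == 0

    def test_info_just_below_threshold_excluded(self):
        m = make_matrix([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [1.0, 1.0]],
                        info=[0.59, 0.9])
        out, report = filter_variants(m, QCThresholds(hwe_alpha=0.0001, min_maf=0.0))
        assert report.excluded_ids("info") == ["rs0"]

    def test_subset_and_idempotent(self):
        m = self._fixture()
        out1, _ = filter_variants(m, QCThresholds())
        out2, rep2 = filter_variants(out1, QCThresholds())
        assert out2.rsids == out1.rsids
        assert rep2.n_excluded == 0

    def test_all_excluded_is_error(self):
        m = make_matrix([[0.0], [0.0], [0.0]])
        with pytest.raises(QCError, match="every variant"):
            filter_variants(m, QCThresholds())


class TestHeterozygosity:
    def test_constant_het_rate_none_excluded(self):
        m = make_matrix([[1.0, 0.0]] * 10)
        excluded, _ = heterozygosity_outliers(m, 3.0)
        assert excluded == []

    def test_extreme_sample_excluded(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(100, 60), p=[0.45, 0.35, 0.2])
        dosage[7] = 1.0  # het rate 1.0 against ~0.35 background
        m = make_matrix(dosage.tolist())
        excluded, rates = heterozygosity_outliers(m, 3.0)
        assert "S7" in excluded
        assert rates["S7"] == 1.0

    def test_infinite_k_excludes_none(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(30, 20)).astype(float)
        m = make_matrix(dosage.tolist())
        excluded, _ = heterozygosity_outliers(m, math.inf)
        assert excluded == []

    def test_under_three_samples_warns(self):
        m = make_matrix([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="fewer than 3"):
            excluded, _ = heterozygosity_outliers(m, 3.0)
        assert excluded == []


class TestRelatedness:
    def test_duplicate_sample_pi_hat_one(self, rng):
        dosage = rng.choice([0.0, 1.0, 2.0], size=(20, 300), p=[0.4, 0.4, 0.2])
        dosage[1] = dosage[0]  # exact duplicate -> PI_HAT at the estimator ceiling
        m = make_matrix(dosage.tolist())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, excluded = relatedness(m)
        pair = table[(table.id1 == "S0") & (table.id2 == "S1")].iloc[0]
        assert pair["pi_hat"] == pytest.approx(1.0, abs=1e-9)
        assert "S0" in excluded or "S1" in excluded

    def test_unrelated_pair_near_zero(self):
        cfg = SimulationConfig(n_variants=1000, block_size=1, maf_range=(0.1, 0.5), seed=21)
        m = simulate_genotypes(cfg, n_samples=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, _ = relatedness(m)
        assert abs(table.iloc[0]["pi_hat"]) < 0.05

    def test_threshold_is_strictly_greater(self):
        # the exclusion rule, fed a pair sitting exactly at 0.125, keeps both
        excl = pi_hat_exclusions(
            [("S0", "S1", 0.125)], {"S0": 0.0, "S1": 0.0}, ["S0", "S1"]
        )
        assert excl == []
        excl = pi_hat_exclusions(
            [("S0", "S1", 0.1251)], {"S0": 0.0, "S1": 0.0}, ["S0", "S1"]
        )
        assert excl == ["S1"]  # tie on missingness -> later sample dropped

    def test_higher_missing_member_dropped(self):
        excl = pi_hat_exclusions(
            [("S0", "S1", 0.9)], {"S0": 0.05, "S1": 0.0}, ["S0", "S1"]
        )
        assert excl == ["S0"]

    def test_monomorphic_only_rejected(self):
        m = make_matrix([[0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        with pytest.raises(QCError, match="polymorphic"):
            relatedness(m)


class TestLDPrune:
    def test_correlated_neighbour_pruned(self, rng):
        a = rng.choice([0.0, 1.0, 2.0], size=200)
        dosage = np.column_stack([a, a, rng.permutation(a)])
        m = make_matrix(dosage.tolist(), pos_step=1000)
        kept = ld_prune(m, r2_threshold=0.2, window_bp=10_000)
        assert kept == [0, 2]

    def test_outside_window_kept(self, rng):
        a = rng.choice([0.0, 1.0, 2.0], size=200)
        m = make_matrix(np.column_stack([a, a]).tolist(), pos_step=500_000)
        assert ld_prune(m) == [0, 1]


class TestSexCheck:
    def _xy_matrix(self, male_rows, reported, rng, n_x=30):
        n = len(reported)
        mafs = rng.uniform(0.25, 0.4, size=n_x)
        dosage = np.empty((n, n_x))
        for j in range(n_x):
            dosage[:, j] = rng.binomial(2, mafs[j], size=n)
            for i in male_rows:
                dosage[i, j] = 2.0 * rng.binomial(1, mafs[j])
        return make_matrix(dosage.tolist(), chrom="X", sexes=reported)

    def test_hemizygous_coding_inferred_male(self, rng):
        m = self._xy_matrix([0], ["male", "female", "female", "female"], rng)
        mismatched, inferred = sex_check(m)
        assert inferred["S0"] == "male"
        assert mismatched == []

    def test_reported_female_with_male_x_flagged(self, rng):
        m = self._xy_matrix([0], ["female", "female", "female", "female"], rng)
        mismatched, inferred = sex_check(m)
        assert mismatched == ["S0"]

    def test_no_x_variants_skips_with_warning(self):
        m = make_matrix([[0.0, 1.0]], chrom="1")
        with pytest.warns(UserWarning, match="sex check skipped"):
            mismatched, inferred = sex_check(m)
        assert mismatched == [] and inferred == {}

    def test_planted_mismatches_recovered_from_truth(self):
        cfg = SimulationConfig(
            n_cases=30, n_controls=50, n_variants=100, block_size=1,
            n_x_variants=40, n_sex_mismatch=3, n_related_pairs=0,
            missing_rate=0.0, seed=31,
        )
        bundle = simulate_cohort(cfg)
        mismatched, _ = sex_check(bundle.matrix)
        assert sorted(mismatched) == sorted(bundle.truth.sex_mismatches)


class TestRunSampleQC:
    def test_clean_cohort_zero_exclusions(self):
        cfg = SimulationConfig(
            n_cases=25, n_controls=40, n_variants=2000, block_size=1,
            missing_rate=0.0, n_related_pairs=0, n_sex_mismatch=0,
            n_x_variants=20, seed=41,
        )
        bundle = simulate_cohort(cfg)
        out, report = run_sample_qc(bundle.matrix, QCThresholds())
        assert report.n_excluded == 0
        assert out.n_samples == 65

    def test_planted_foils_attributed_correctly(self):
        cfg = SimulationConfig(
            n_cases=30, n_controls=50, n_variants=2000, block_size=1,
            missing_rate=0.0, n_related_pairs=2, relative_copy_fidelity=1.0,
            n_sex_mismatch=1, n_x_variants=40, seed=43,
        )
        bundle = simulate_cohort(cfg)
        out, report = run_sample_qc(bundle.matrix, QCThresholds())
        by_stage = report.counts_by_stage()
        assert by_stage.get("relatedness", 0) == 2
        assert by_stage.get("sex", 0) + by_stage.get("heterozygosity", 0) >= 1
        rel_ids = set(report.excluded_ids("relatedness"))
        truth_members = {m for pair in bundle.truth.related_pairs for m in pair}
        assert rel_ids <= truth_members
        sex_ids = set(report.excluded_ids("sex"))
        assert sex_ids <= set(bundle.truth.sex_mismatches)

    def test_loosened_thresholds_exclude_nothing(self):
        cfg = SimulationConfig(
            n_cases=15, n_controls=25, n_variants=300, block_size=1,
            n_related_pairs=1, relative_copy_fidelity=1.0, n_sex_mismatch=1,
            n_x_variants=20, seed=47,
        )
        bundle = simulate_cohort(cfg)
        loose = QCThresholds(
            max_sample_missing=1.0, max_relatedness=1.0, het_sd_k=1e9
        )
        # sex check has no threshold; run with X variants renamed off-X
        from dataclasses import replace

        m = bundle.matrix
        m.variants = [
            replace(v, chrom="21") if v.chrom == "X" else v for v in m.variants
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, report = run_sample_qc(m, loose)
        assert report.n_excluded == 0


def test_genotype_counts_ignore_missing():
    assert genotype_counts([0, 1, 2, np.nan, 1]) == (1, 2, 1)
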