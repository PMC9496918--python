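import numpy as np
import pytest

import mtbfocus as m
from mtbfocus.simulate import (DEFAULT_PFS_DISTRIBUTIONS, cohort_frame,
                               expected_normal_counts, tumor_expected_counts)


def flat_binning(n_bins=1000, width=1000):
    return m.toy_binning(n_contigs=1, contig_length=n_bins * width, bin_width=width)


class TestNormalProfiles:
    def test_same_seed_gives_identical_profiles(self):
        binning = flat_binning(100)
        cfg = m.SimulationConfig(seed=9, total_reads=10_000, n_normals=4)
        a = m.simulate_normal_profiles(binning, cfg)
        b = m.simulate_normal_profiles(binning, cfg)
        for pa, pb in zip(a, b):
            assert (pa.counts == pb.counts).all()
            assert pa.sex == pb.sex

    def test_mean_counts_match_analytic_expectation(self):
        # 1,000 equal-width autosomal bins, uniform gc, 100,000 reads:
        # each bin's expectation is 100; the mean over 50 Poisson replicates
        # has standard error sqrt(100/50)
        binning = flat_binning(1000)
        reps = [m.simulate_normal_profiles(
            binning, m.SimulationConfig(seed=s, total_reads=100_000, n_normals=1))[0]
            for s in range(50)]
        means = np.stack([p.counts for p in reps]).mean(axis=0)
        se = np.sqrt(100 / 50)
        z = np.abs(means - 100) / se
        assert (z < 3).mean() > 0.99  # per-bin 3-SE check, allowing chance excursions
        assert z.max() < 5

    def test_expected_totals_sum_to_total_reads(self):
        binning = m.default_binning(25_000_000)
        cfg = m.SimulationConfig(seed=0, total_reads=123_456)
        for sex in ("male", "female"):
            lam = expected_normal_counts(binning, cfg, sex)
            assert lam.sum() == pytest.approx(cfg.total_reads, rel=1e-6)

    def test_sex_appropriate_xy_dosage(self):
        binning = m.default_binning(25_000_000)
        cfg = m.SimulationConfig(seed=0, total_reads=1_000_000)
        contigs = binning.contig_of_bins()
        lam_m = expected_normal_counts(binning, cfg, "male")
        lam_f = expected_normal_counts(binning, cfg, "female")
        assert (lam_f[contigs == "chrY"] == 0).all()
        ratio = lam_m[contigs == "chrX"].sum() / lam_f[contigs == "chrX"].sum()
        # male X has half dosage (before total-count renormalization ~ +2.5%)
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_non_positive_total_reads_rejected(self):
        with pytest.raises(ValueError):
            m.SimulationConfig(seed=0, total_reads=0)


class TestTumorProfiles:
    def test_purity_one_multiplier_is_cn_over_two(self):
        binning = flat_binning(30)
        cfg = m.SimulationConfig(seed=1, total_reads=30_000)
        truth = m.KaryotypeTruth(
            events=(m.CnEvent("chr1", 10_000, 20_000, 3),), purity=1.0)
        lam = tumor_expected_counts(binning, truth, cfg)
        base = expected_normal_counts(binning, cfg, "female")
        assert np.allclose(lam[10:20] / base[10:20], 1.5)
        assert np.allclose(lam[:10] / base[:10], 1.0)

    def test_purity_zero_matches_normal_expectation(self):
        binning = flat_binning(30)
        cfg = m.SimulationConfig(seed=1, total_reads=30_000)
        truth = m.KaryotypeTruth(
            events=(m.CnEvent("chr1", 0, 30_000, 5),), purity=0.0)
        lam = tumor_expected_counts(binning, truth, cfg)
        assert np.allclose(lam, expected_normal_counts(binning, cfg, "female"))

    def test_half_purity_homozygous_deletion_halves_expectation(self):
        binning = flat_binning(30)
        cfg = m.SimulationConfig(seed=1, total_reads=30_000)
        truth = m.KaryotypeTruth(
            events=(m.CnEvent("chr1", 0, 10_000, 0),), purity=0.5)
        lam = tumor_expected_counts(binning, truth, cfg)
        base = expected_normal_counts(binning, cfg, "female")
        assert np.allclose(lam[:10] / base[:10], 0.5)

    def test_rescaling_restores_total_and_is_recorded(self):
        binning = flat_binning(30)
        cfg = m.SimulationConfig(seed=1, total_reads=30_000)
        truth = m.KaryotypeTruth(
            events=(m.CnEvent("chr1", 0, 30_000, 4),), purity=1.0)
        lam = tumor_expected_counts(binning, truth, cfg, rescale=True)
        assert lam.sum() == pytest.approx(30_000, rel=1e-6)
        prof, _ = m.simulate_tumor_profile(binning, truth, cfg, rescale=True)
        assert prof.meta["rescaled"] is True

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            m.KaryotypeTruth(events=(), purity=1.5)
        with pytest.raises(ValueError):
            m.KaryotypeTruth(events=(m.CnEvent("chr1", 0, 100, 2),
                                     m.CnEvent("chr1", 50, 150, 3)), purity=1.0)


class TestVariantTable:
    def test_empty_request_gives_empty_table(self):
        table, labels = m.simulate_variant_table(0, m.SimulationConfig(seed=0))
        assert table.empty and labels.size == 0

    def test_fixed_seed_is_deterministic(self):
        cfg = m.SimulationConfig(seed=4)
        t1, l1 = m.simulate_variant_table(50, cfg)
        t2, l2 = m.simulate_variant_table(50, cfg)
        assert t1.equals(t2) and (l1 == l2).all()

    def test_oracle_evaluates_the_three_predicates(self):
        assert m.variant_pass_oracle(np.array([150.0]), np.array([0.10]),
                                     np.array([0.001]))[0]
        assert not m.variant_pass_oracle(np.array([150.0]), np.array([0.10]),
                                         np.array([0.20]))[0]
        assert not m.variant_pass_oracle(np.array([100.0]), np.array([0.10]),
                                         np.array([np.nan]))[0]
        assert m.variant_pass_oracle(np.array([101.0]), np.array([0.05]),
                                     np.array([np.nan]))[0]

    def test_boundary_values_appear_in_output(self):
        table, _ = m.simulate_variant_table(500, m.SimulationConfig(seed=2))
        assert (table["depth"] == 100).any()
        assert (table["vaf"] == 0.05).any()
        assert (table["popfreq"] == 0.05).any()
        assert table["popfreq"].isna().any()


class TestCohort:
    def test_empty_cohort(self):
        assert m.simulate_cohort(0, 0, m.SimulationConfig(seed=0)) == []

    def test_fixed_seed_gives_identical_cohorts(self):
        cfg = m.SimulationConfig(seed=8)
        a = cohort_frame(m.simulate_cohort(10, 10, cfg))
        b = cohort_frame(m.simulate_cohort(10, 10, cfg))
        assert a.equals(b)

    def test_km_median_matches_generating_distribution(self):
        # exponential PFS2 with median 4.3 in the matched arm: KM median over
        # 200 patients should land within 15%
        cfg = m.SimulationConfig(seed=6)
        records = m.simulate_cohort(200, 0, cfg)
        est = m.km_estimate([r.pfs2 for r in records],
                            [r.event for r in records])
        assert est.median == pytest.approx(
            DEFAULT_PFS_DISTRIBUTIONS["matched"]["median"], rel=0.15)

    def test_flags_never_inconsistent(self):
        records = m.simulate_cohort(100, 50, m.SimulationConfig(seed=13),
                                    censor_rate=0.2)
        for r in records:
            assert not (r.clinical_response and r.toxicity_stop)
            assert r.pfs1 > 0 and r.pfs2 > 0
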