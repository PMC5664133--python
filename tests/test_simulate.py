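import numpy as np
import pandas as pd
import pytest

from aeiscan import (
    AllelicImbalanceModel,
    SimConfig,
    simulate_cohort,
    truth_eval,
)
from aeiscan.detection import FilterConfig, passes_filters
from aeiscan.simulate import read_truth, write_truth


class TestConfigValidation:
    def test_zero_variants_rejected(self):
        with pytest.raises(ValueError, match="at least one variant"):
            SimConfig(n_null_variants=0, n_aei_variants=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"marker_af": 0.0},
            {"aei_fraction": 1.0},
            {"rho": 1.0},
            {"ld_r2": 1.5},
            {"mean_depth": -1.0},
            {"n_samples": 0},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(n_null_variants=20, n_aei_variants=10, seed=5)
        t1, truth1 = simulate_cohort(cfg)
        t2, truth2 = simulate_cohort(cfg)
        assert t1 == t2
        pd.testing.assert_frame_equal(truth1.variants, truth2.variants)
        pd.testing.assert_frame_equal(truth1.samples, truth2.samples)

    def test_different_seed_differs(self):
        t1, _ = simulate_cohort(SimConfig(n_null_variants=20, n_aei_variants=0, seed=1))
        t2, _ = simulate_cohort(SimConfig(n_null_variants=20, n_aei_variants=0, seed=2))
        assert t1 != t2

    def test_adding_variants_preserves_earlier_substreams(self):
        small, _ = simulate_cohort(SimConfig(n_null_variants=10, n_aei_variants=0, seed=3))
        large, _ = simulate_cohort(SimConfig(n_null_variants=25, n_aei_variants=0, seed=3))
        for site in small.sites:
            for sample in small.samples:
                a = small.get(site, sample)
                b = large.get(site, sample)
                assert (a.ref_count, a.alt_count, a.genotype) == (
                    b.ref_count,
                    b.alt_count,
                    b.genotype,
                )


class TestStatisticalStructure:
    def test_truth_aligns_with_emitted_records(self, default_cohort):
        table, truth = default_cohort
        assert len(truth.variants) == len(table.sites)
        assert len(truth.samples) == len(table)
        assert set(truth.variants["rsid"]) == {s.rsid for s in table.sites}

    def test_deep_null_cohort_concentrates_in_balance_band(self):
        # without overdispersion and at very high depth, balanced het
        # ratios concentrate tightly around 1
        cfg = SimConfig(
            n_samples=52,
            n_null_variants=50,
            n_aei_variants=0,
            mean_depth=10_000.0,
            rho=0.0,
            seed=9,
        )
        table, _ = simulate_cohort(cfg)
        ratios = [
            r.alt_count / r.ref_count
            for r in table
            if r.genotype == "het" and r.ref_count > 0
        ]
        inside = [r for r in ratios if 0.666 <= r <= 1.5]
        assert len(inside) / len(ratios) >= 0.99

    def test_aei_fraction_half_is_null_equivalent_but_labelled(self):
        cfg = SimConfig(
            n_null_variants=5, n_aei_variants=5, aei_fraction=0.4999999, seed=4
        )
        _, truth = simulate_cohort(cfg)
        assert truth.variants["is_aei"].sum() == 5
        het = truth.samples.dropna(subset=["expressed_alt_fraction"])
        assert np.allclose(het["expressed_alt_fraction"].abs(), 0.5, atol=1e-6)

    def test_phase_orients_expression(self, default_cohort):
        _, truth = default_cohort
        het = truth.samples[truth.samples["genotype"] == "het"]
        alt_phase = het[het["phase"] == "alt"]
        ref_phase = het[het["phase"] == "ref"]
        assert (alt_phase["expressed_alt_fraction"] == 0.30).all()
        assert (ref_phase["expressed_alt_fraction"] == 0.70).all()
        # complete LD with equal allele frequencies: every het sample of an
        # AEI variant carries the repressive allele on the alt haplotype
        aei_ids = set(
            truth.variants.loc[truth.variants["is_aei"], "rsid"]
        )
        aei_het = het[het["rsid"].isin(aei_ids)]
        assert set(aei_het["phase"]) == {"alt"}

    def test_low_depth_fraction_exercises_depth_filter(self):
        cfg = SimConfig(
            n_null_variants=30,
            n_aei_variants=0,
            low_depth_fraction=0.3,
            seed=6,
        )
        table, _ = simulate_cohort(cfg)
        depths = [r.depth for r in table]
        assert any(d < 20 for d in depths)
        shallow = [r for r in table if r.depth < 20]
        assert all(not passes_filters(r, FilterConfig()) for r in shallow)

    def test_qual_above_default_threshold(self, default_cohort):
        table, _ = default_cohort
        assert all(s.qual > 225 for s in table.sites)


class TestTruthEval:
    def test_perfect_detection(self, default_cohort):
        _, truth = default_cohort
        aei = set(truth.variants.loc[truth.variants["is_aei"], "rsid"])
        metrics = truth_eval(aei, truth)
        assert metrics.sensitivity == 1.0
        assert metrics.false_positive_rate == 0.0

    def test_detecting_nothing(self, default_cohort):
        _, truth = default_cohort
        metrics = truth_eval(set(), truth)
        assert metrics.sensitivity == 0.0
        assert metrics.fp == 0

    def test_matches_brute_force_confusion_tally(self, default_cohort, rng):
        _, truth = default_cohort
        ids = list(truth.variants["rsid"])
        detected = set(rng.choice(ids, size=60, replace=False))
        metrics = truth_eval(detected, truth)
        is_aei = dict(zip(truth.variants["rsid"], truth.variants["is_aei"]))
        tp = sum(1 for r in ids if is_aei[r] and r in detected)
        fp = sum(1 for r in ids if not is_aei[r] and r in detected)
        fn = sum(1 for r in ids if is_aei[r] and r not in detected)
        tn = sum(1 for r in ids if not is_aei[r] and r not in detected)
        assert (metrics.tp, metrics.fp, metrics.fn, metrics.tn) == (tp, fp, fn, tn)

    def test_unknown_variant_rejected(self, default_cohort):
        _, truth = default_cohort
        with pytest.raises(ValueError, match="not in truth"):
            truth_eval({"rs_not_simulated"}, truth)

    def test_truth_roundtrip(self, tmp_path, default_cohort):
        _, truth = default_cohort
        write_truth(truth, tmp_path / "v.tsv", tmp_path / "s.tsv")
        back = read_truth(tmp_path / "v.tsv", tmp_path / "s.tsv")
        assert list(back.variants["rsid"]) == list(truth.variants["rsid"])
        assert list(back.variants["is_aei"]) == list(truth.variants["is_aei"])


def _sensitivity(frac=0.3, depth=80.0, seed=11):
    cfg = SimConfig(
        n_null_variants=100,
        n_aei_variants=40,
        aei_fraction=frac,
        mean_depth=depth,
        seed=seed,
    )
    table, truth = simulate_cohort(cfg)
    results = AllelicImbalanceModel(table, cohort_size=52).fit()
    return results.evaluate(truth).sensitivity


class TestDetectionMonotonicity:
    def test_sensitivity_grows_with_effect_size(self):
        s_half = _sensitivity(frac=0.5)
        s_mid = _sensitivity(frac=0.35)
        s_strong = _sensitivity(frac=0.2)
        assert s_half <= s_mid <= s_strong

    def test_sensitivity_nondecreasing_with_depth(self):
        s30 = _sensitivity(depth=30.0)
        s80 = _sensitivity(depth=80.0)
        s200 = _sensitivity(depth=200.0)
        assert s30 <= s80 <= s200
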