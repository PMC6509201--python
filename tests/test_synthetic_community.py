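import numpy as np
import pytest

from thermotrace.calling import call_thermospores
from thermotrace.synthetic_community import (
    CommunitySimConfig,
    ThermosporeClass,
    apply_pretreatment,
    default_classes,
    draw_seedbank,
    generate_study,
    incubate,
    recovery_summary,
    sequence_sample,
)
from thermotrace.types import ConfigError, Pretreatment, ValidationError


def uniform_survival(p4, m20, m80, label="cls"):
    return ThermosporeClass(
        label,
        {
            Pretreatment.PLUS4: p4,
            Pretreatment.MINUS20: m20,
            Pretreatment.MINUS80: m80,
        },
    )


class TestSeedbank:
    def test_composition_normalized_and_sized(self):
        cfg = CommunitySimConfig(n_background_otus=300, n_thermospore_otus=20, seed=0)
        truth = draw_seedbank(cfg, np.random.default_rng(0))
        assert len(truth.otu_ids) == 320
        assert truth.day0_composition.sum() == pytest.approx(1.0, abs=1e-12)
        assert truth.is_thermospore.sum() == 20

    def test_seed_fractions_within_range(self):
        cfg = CommunitySimConfig(seed=1)
        truth = draw_seedbank(cfg, np.random.default_rng(1))
        seeds = truth.day0_composition[truth.is_thermospore]
        lo, hi = cfg.seed_fraction_range
        assert np.all((seeds >= lo) & (seeds <= hi))

    def test_no_thermospores_all_background(self):
        cfg = CommunitySimConfig(n_thermospore_otus=0, seed=2)
        truth = draw_seedbank(cfg, np.random.default_rng(2))
        assert not truth.is_thermospore.any()
        assert all(lbl is None for lbl in truth.class_labels)

    def test_empty_community_rejected(self):
        with pytest.raises(ConfigError):
            CommunitySimConfig(n_background_otus=0, n_thermospore_otus=0)

    def test_same_rng_state_reproduces_truth(self):
        cfg = CommunitySimConfig(seed=3)
        t1 = draw_seedbank(cfg, np.random.default_rng(9))
        t2 = draw_seedbank(cfg, np.random.default_rng(9))
        assert np.array_equal(t1.day0_composition, t2.day0_composition)
        assert np.array_equal(t1.growth_factor, t2.growth_factor)


class TestPretreatmentAndIncubation:
    def test_certain_survival_changes_nothing(self):
        cfg = CommunitySimConfig(
            n_background_otus=50,
            n_thermospore_otus=6,
            classes=(uniform_survival(1.0, 1.0, 1.0),),
            seed=4,
        )
        truth = draw_seedbank(cfg, np.random.default_rng(4))
        mc = apply_pretreatment(
            truth, cfg, Pretreatment.MINUS80, "R1", np.random.default_rng(5)
        )
        assert mc.survived.all()
        assert np.array_equal(
            mc.realized_growth, truth.growth_factor[truth.is_thermospore]
        )

    def test_certain_death_means_no_enrichment(self):
        cfg = CommunitySimConfig(
            n_background_otus=50,
            n_thermospore_otus=6,
            classes=(uniform_survival(1.0, 1.0, 0.0, "freeze_sensitive"),),
            seed=6,
        )
        truth = draw_seedbank(cfg, np.random.default_rng(6))
        mc = apply_pretreatment(
            truth, cfg, Pretreatment.MINUS80, "R1", np.random.default_rng(7)
        )
        mc = incubate(truth, mc)
        assert not mc.survived.any()
        assert np.allclose(mc.day7_composition, mc.day0_composition)

    def test_survival_probability_calibrated(self):
        # class with survival 0.5 at -80C: Monte-Carlo mean within 3 SE
        cfg = CommunitySimConfig(
            n_background_otus=10,
            n_thermospore_otus=1,
            classes=(uniform_survival(1.0, 1.0, 0.5),),
            seed=8,
        )
        truth = draw_seedbank(cfg, np.random.default_rng(8))
        n = 1000
        rng = np.random.default_rng(42)
        survived = sum(
            apply_pretreatment(truth, cfg, Pretreatment.MINUS80, "R1", rng).survived[0]
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(survived / n - 0.5) < 3 * se

    def test_unit_growth_is_identity(self):
        cfg = CommunitySimConfig(
            n_background_otus=30,
            n_thermospore_otus=4,
            classes=(
                ThermosporeClass(
                    "no_growth",
                    {p: 1.0 for p in Pretreatment},
                    growth_range=(1.0, 1.0),
                ),
            ),
            seed=9,
        )
        truth = draw_seedbank(cfg, np.random.default_rng(9))
        mc = incubate(
            truth,
            apply_pretreatment(
                truth, cfg, Pretreatment.PLUS4, "R1", np.random.default_rng(10)
            ),
        )
        assert np.allclose(mc.day7_composition, mc.day0_composition, atol=1e-15)

    def test_single_otu_enrichment_closed_form(self):
        # seed 0.001 growing 1000x against background 0.999:
        # day-7 fraction = 1/(0.999 + 1) ~ 0.5003
        cfg = CommunitySimConfig(n_background_otus=1, n_thermospore_otus=1, seed=0)
        truth = draw_seedbank(cfg, np.random.default_rng(0))
        truth.day0_composition = np.array([0.999, 0.001])
        truth.growth_factor[:] = [1.0, 1000.0]
        mc = apply_pretreatment(
            truth, cfg, Pretreatment.PLUS4, "R1", np.random.default_rng(1)
        )
        mc.realized_growth[:] = 1000.0
        mc.day0_composition = truth.day0_composition
        mc = incubate(truth, mc)
        assert mc.day7_composition[1] == pytest.approx(1.0 / 1.999, rel=1e-12)
        assert mc.day7_composition.sum() == pytest.approx(1.0, abs=1e-12)


class TestSequencing:
    def test_degenerate_composition(self):
        counts = sequence_sample(np.array([1.0]), 45000, np.random.default_rng(0))
        assert counts.tolist() == [45000]

    def test_depth_always_exact_and_frequencies_converge(self):
        rng = np.random.default_rng(1)
        counts = sequence_sample(np.array([0.5, 0.5]), 45000, rng)
        assert counts.sum() == 45000
        se = np.sqrt(0.25 / 45000)
        assert abs(counts[0] / 45000 - 0.5) < 3 * se

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError):
            sequence_sample(np.array([-0.1, 1.1]), 100, rng)
        with pytest.raises(ValidationError):
            sequence_sample(np.array([1.0]), 0, rng)


class TestGenerateStudy:
    def test_design_shape(self, small_study):
        table, meta, truth = small_study
        assert table.n_samples == 18
        assert len(meta) == 18
        assert len(truth.microcosms) == 9
        assert np.all(table.library_sizes().to_numpy() == 8000)

    def test_determinism_bit_identical(self, small_sim_config):
        t1, m1, _ = generate_study(small_sim_config)
        t2, m2, _ = generate_study(small_sim_config)
        assert np.array_equal(t1.counts.to_numpy(), t2.counts.to_numpy())
        assert m1 == m2

    def test_adding_replicates_preserves_earlier_draws(self):
        base = CommunitySimConfig(
            n_background_otus=40, n_thermospore_otus=4, library_size=2000,
            replicates=2, seed=12,
        )
        import dataclasses

        more = dataclasses.replace(base, replicates=3)
        t1, _, _ = generate_study(base)
        t2, _, _ = generate_study(more)
        shared = [c for c in t1.sample_ids]
        assert np.array_equal(
            t1.counts[shared].to_numpy(), t2.counts[shared].to_numpy()
        )

    def test_thermospore_bloom_exceeds_tenfold(self, default_study):
        # the thermospore fraction after incubation dwarfs the seed bank
        table, meta, truth = default_study
        ts = truth.thermospore_ids
        rel = table.counts / table.counts.sum(axis=0)
        day0 = [r.sample_id for r in meta if r.timepoint_days == 0]
        day7 = [r.sample_id for r in meta if r.timepoint_days == 7]
        assert rel.loc[ts, day7].sum(axis=0).mean() > 10 * rel.loc[ts, day0].sum(axis=0).mean()

    def test_recovery_with_defaults(self, default_study):
        table, meta, truth = default_study
        calls = call_thermospores(table, meta)
        rs = recovery_summary(calls, truth)
        assert rs["false_positive_background"] == []
        assert rs["recovery_rate"] > 0.9

    def test_lower_survival_cannot_increase_detections(self):
        # Monte-Carlo mean of -80C detections under survival 0.9 vs 0.2
        def mean_detections(p80, seeds):
            total = 0
            for seed in seeds:
                cfg = CommunitySimConfig(
                    n_background_otus=60,
                    n_thermospore_otus=6,
                    classes=(uniform_survival(0.95, 0.95, p80),),
                    library_size=6000,
                    seed=seed,
                )
                table, meta, truth = generate_study(cfg)
                calls = call_thermospores(table, meta)
                for c in calls:
                    total += sum(
                        t.qualifies
                        for mc, t in c.per_microcosm.items()
                        if mc.startswith("MINUS80")
                    )
            return total / len(seeds)

        seeds = range(100, 110)
        assert mean_detections(0.9, seeds) >= mean_detections(0.2, seeds)
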