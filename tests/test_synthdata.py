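import numpy as np
import pytest

from fancfid.errors import ConfigError
from fancfid.fidelity import cohort_fidelity, woman_fidelity
from fancfid.records import FACILITATION_ITEMS, facilitation_score, write_cohort
from fancfid.synthdata import (
    DEFAULT_CONTENT_PROBS,
    GeneratorConfig,
    generate_clusters,
    generate_cohort_linear,
    generate_cohort_structural,
    linear_variances,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_clusters=1),
            dict(coverage_prob=1.2),
            dict(visit_mean=0.5),
            dict(mode="other"),
            dict(icc_target=1.0),
            dict(total_var=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kwargs)

    def test_variance_calibration_needs_room(self):
        with pytest.raises(ConfigError, match="no room"):
            linear_variances(GeneratorConfig(total_var=0.002))


class TestClusters:
    def test_seed_determinism(self):
        a = generate_clusters(GeneratorConfig(seed=5))
        b = generate_clusters(GeneratorConfig(seed=5))
        assert a == b
        c = generate_clusters(GeneratorConfig(seed=6))
        assert a != c

    def test_all_items_on_gives_full_score(self):
        cfg = GeneratorConfig(
            seed=1, facilitation_probs={k: 1.0 for k in FACILITATION_ITEMS}
        )
        for rec in generate_clusters(cfg).values():
            assert facilitation_score(rec) == 7

    def test_scores_vary_across_clusters(self):
        # facilitation spread is needed for the level-2 covariate to be informative
        hits = 0
        for seed in range(40):
            scores = {
                facilitation_score(c)
                for c in generate_clusters(GeneratorConfig(seed=seed)).values()
            }
            hits += len(scores) >= 2
        assert hits >= 38


class TestStructuralMode:
    def test_saturated_cascade_scores_one(self):
        cfg = GeneratorConfig(
            seed=2,
            n_women=60,
            coverage_prob=1.0,
            content_probs={k: 1.0 for k in DEFAULT_CONTENT_PROBS},
            visit_min=4,
            visit_mean=5.0,
            visit_max=8,
        )
        cohort = generate_cohort_structural(cfg)
        for w in cohort.women:
            assert woman_fidelity(w).fidelity == 1.0

    def test_zero_coverage_cohort_scores_zero(self):
        cfg = GeneratorConfig(seed=2, n_women=40, coverage_prob=0.0)
        cohort = generate_cohort_structural(cfg)
        assert all(w.n_visits == 0 for w in cohort.women)
        assert cohort_fidelity(cohort).mean == 0.0

    def test_marginals_recovered_at_survey_size(self):
        # pooled over a few seeds: binomial tolerance around configured margins
        covs, visits, contents = [], [], []
        for seed in range(8):
            cohort = generate_cohort_structural(GeneratorConfig(seed=seed))
            att = cohort.attenders()
            covs.append(len(att) / cohort.n_women)
            visits.append(np.mean([w.n_visits for w in att]))
            contents.append(np.mean([w.contents.weight_measured for w in att]))
        assert np.mean(covs) == pytest.approx(0.837, abs=0.02)
        assert np.mean(visits) == pytest.approx(3.0, abs=0.1)
        assert np.mean(contents) == pytest.approx(DEFAULT_CONTENT_PROBS["weight_measured"], abs=0.03)

    def test_content_rises_with_visits(self):
        cohort = generate_cohort_structural(GeneratorConfig(seed=4, n_women=3000))
        att = cohort.attenders()
        low = np.mean([w.contents.n_delivered for w in att if w.n_visits <= 2])
        high = np.mean([w.contents.n_delivered for w in att if w.n_visits >= 4])
        assert high > low

    def test_seed_determinism_byte_for_byte(self, tmp_path):
        for tag, seed in (("a", 9), ("b", 9), ("c", 10)):
            write_cohort(
                generate_cohort_structural(GeneratorConfig(seed=seed, n_women=120)),
                tmp_path / f"w_{tag}.csv",
                tmp_path / f"c_{tag}.csv",
            )
        assert (tmp_path / "w_a.csv").read_bytes() == (tmp_path / "w_b.csv").read_bytes()
        assert (tmp_path / "w_a.csv").read_bytes() != (tmp_path / "w_c.csv").read_bytes()


class TestLinearMode:
    def test_noiseless_limit_equals_linear_predictor(self):
        cfg = GeneratorConfig(
            seed=3, n_women=50, mode="linear", sigma_u2=0.0, sigma_e2=1e-18
        )
        sim = generate_cohort_linear(cfg)
        fac = {
            cid: facilitation_score(c) for cid, c in sim.cohort.clusters.items()
        }
        for w, y in zip(sim.cohort.women, sim.response):
            expected = (
                0.35
                + 0.09 * bool(w.prior_pregnancy_problems)
                + 0.08 * (w.partner_education.value == "FORMAL_1_8")
                + 0.04 * fac[w.cluster_id]
            )
            assert y == pytest.approx(min(1.0, max(0.0, expected)), abs=1e-6)

    def test_truncation_warning_when_noise_dominates(self):
        cfg = GeneratorConfig(seed=3, n_women=200, mode="linear", sigma_u2=0.0, sigma_e2=1.0)
        with pytest.warns(UserWarning, match="truncation"):
            generate_cohort_linear(cfg)

    def test_default_truncation_is_rare(self):
        sim = generate_cohort_linear(GeneratorConfig(seed=8, mode="linear"))
        assert sim.truth.n_truncated / sim.cohort.n_women < 0.02

    def test_calibrated_variances_positive_and_ratio_below_target(self):
        su2, se2 = linear_variances(GeneratorConfig())
        assert su2 > 0 and se2 > 0
        # covariates contribute the rest of the between/within shares
        assert su2 / (su2 + se2) < 0.177

    def test_truth_sidecar_is_generating_config(self):
        sim = generate_cohort_linear(GeneratorConfig(seed=12, mode="linear"))
        assert sim.truth.beta["facilitation_score"] == 0.04
        assert set(sim.truth.cluster_effects) == set(sim.cohort.clusters)
        assert len(sim.response) == sim.cohort.n_women
        assert np.all((sim.response >= 0) & (sim.response <= 1))
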