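import json

import numpy as np
import pytest

from farmsustain.ahp import aggregate_judgments, priority_weights
from farmsustain.sustainability_index import load_schema
from farmsustain.synthetic import (
    DEA_INPUT_COLUMNS,
    GeneratorConfig,
    generate_expert_matrices,
    generate_farms,
    generate_population_strata,
    simulate_tobit,
    write_farm_table,
)


class TestGenerateFarms:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=42)
        p1 = write_farm_table(generate_farms(cfg), tmp_path / "a.csv")
        p2 = write_farm_table(generate_farms(cfg), tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()
        t1 = json.loads((tmp_path / "a.truth.json").read_text())
        t2 = json.loads((tmp_path / "b.truth.json").read_text())
        assert t1 == t2

    def test_different_seeds_differ(self):
        a = generate_farms(GeneratorConfig(seed=1)).frame
        b = generate_farms(GeneratorConfig(seed=2)).frame
        assert not a.equals(b)

    def test_no_inefficiency_limit(self):
        truth = {"slopes": {}, "sigma": 0.0}
        cfg = GeneratorConfig(inefficiency_scale=0.0, tobit_truth=truth)
        data = generate_farms(cfg)
        np.testing.assert_allclose(data.true_efficiency, 1.0)

    def test_positivity_and_domains(self):
        f = generate_farms(GeneratorConfig(seed=5)).frame
        assert (f["gpv"] > 0).all()
        for c in DEA_INPUT_COLUMNS:
            assert (f[c] >= 0).all()
        assert set(f["nonfarm_income"].unique()) <= {0.0, 1.0}
        assert f["education_level"].between(0, 5).all()

    def test_indicator_values_in_schema_range(self):
        f = generate_farms(GeneratorConfig(seed=9)).frame
        for d in load_schema():
            col = f[d.name]
            if d.scale == "binary":
                assert set(col.unique()) <= {0.0, 1.0}, d.name
            elif d.scale == "likert5":
                assert col.between(1, 5).all(), d.name
            elif d.scale == "frequency6":
                assert col.between(1, 6).all(), d.name

    def test_mean_gpv_calibration_envelope(self):
        # Across replicate populations the mean GPV stays within 50% of
        # the survey mean it is calibrated towards.
        means = [
            generate_farms(GeneratorConfig(seed=s)).frame["gpv"].mean() for s in range(200)
        ]
        assert abs(np.mean(means) - 13800.569) / 13800.569 < 0.5

    def test_efficiency_truth_links_to_dea_scores(self):
        # Known-truth sanity link: generated true efficiency and DEA
        # scores agree in rank on average.
        from scipy.stats import spearmanr

        from farmsustain.dea import DEAProblem, solve_input_oriented

        corrs = []
        for s in range(20):
            data = generate_farms(GeneratorConfig(seed=3000 + s, inefficiency_scale=0.3))
            prob = DEAProblem(
                data.frame[list(DEA_INPUT_COLUMNS)].to_numpy(),
                data.frame["gpv"].to_numpy(),
            )
            theta = solve_input_oriented(prob).theta
            corrs.append(spearmanr(data.true_efficiency, theta).statistic)
        assert np.mean(corrs) > 0.7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_farms=2, n_strata=5)
        with pytest.raises(ValueError):
            GeneratorConfig(indicator_priors={"x": ("bernoulli", 1.5)})
        with pytest.raises(ValueError):
            GeneratorConfig(production_elasticities={"roughage_kg": -0.1})


class TestExpertMatrices:
    def test_noiseless_case_is_exactly_consistent(self):
        mats = generate_expert_matrices(5, (0.5, 0.25, 0.25), perturbation_sd=0.0, seed=3)
        for m in mats:
            w = np.array([0.5, 0.25, 0.25])
            np.testing.assert_allclose(m.values, w[:, None] / w[None, :])

    def test_reciprocity_by_construction(self):
        mats = generate_expert_matrices(10, (0.45, 0.35, 0.20), perturbation_sd=0.4, seed=4)
        for m in mats:
            np.testing.assert_allclose(m.values * m.values.T, 1.0, atol=1e-12)

    def test_aggregation_recovers_true_weights(self):
        w_true = np.array([0.5, 0.25, 0.25])
        mats = generate_expert_matrices(17, w_true, perturbation_sd=0.1, seed=8)
        w_hat = priority_weights(aggregate_judgments(mats))
        assert np.max(np.abs(w_hat - w_true)) < 0.05

    def test_determinism(self):
        a = generate_expert_matrices(3, (0.4, 0.4, 0.2), 0.2, seed=7)
        b = generate_expert_matrices(3, (0.4, 0.4, 0.2), 0.2, seed=7)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.values, mb.values)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            generate_expert_matrices(3, (0.5, -0.1, 0.6), 0.1, seed=1)


class TestPopulationStrata:
    def test_single_stratum(self):
        strata = generate_population_strata(1, [100], [5.0])
        assert strata[0].Nh == 100 and strata[0].Sh == 5.0

    def test_zero_strata_rejected(self):
        with pytest.raises(ValueError):
            generate_population_strata(0, [], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_population_strata(2, [10], [1.0, 2.0])

    def test_population_total_preserved(self):
        sizes = [40, 60, 100]
        strata = generate_population_strata(3, sizes, [1.0, 2.0, 3.0])
        assert sum(s.Nh for s in strata) == sum(sizes)


class TestSimulateTobit:
    def test_shapes_and_censoring(self):
        y, X = simulate_tobit(500, [0.8, -0.2, 0.15], 0.15, seed=1)
        assert y.shape == (500,) and X.shape == (500, 3)
        assert (y >= 0).all() and (y <= 1).all()
        assert (y == 1).sum() > 0  # right-censoring present at these settings
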