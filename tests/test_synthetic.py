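"""Synthetic dyad generator: determinism, dwell/length models, planted effects."""

import numpy as np
import pytest

from dyadnet import (
    ConfigError,
    GROUP_A,
    GROUP_B,
    PlantedDifference,
    Transition,
    expected_rates,
    generate_streams,
    harmonious_config,
    make_planted_config,
    stationary_distribution,
    uniform_config,
    validate_stream,
)
from dyadnet.synthetic import GroupDynamics, SyntheticConfig


class TestConfigValidation:
    def test_non_stochastic_matrix_rejected(self):
        cfg = uniform_config(n_states=3)
        bad = np.array([[0, 0.5, 0.4], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ConfigError, match="sum to 1"):
            SyntheticConfig(
                states=cfg.states,
                group_a=GroupDynamics(5, bad, cfg.group_a.initial_dist,
                                      cfg.group_a.persistence),
                group_b=cfg.group_b,
            )

    def test_self_transitions_rejected(self):
        cfg = uniform_config(n_states=3)
        bad = np.array([[0.2, 0.4, 0.4], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ConfigError, match="self-transitions"):
            SyntheticConfig(
                states=cfg.states,
                group_a=GroupDynamics(5, bad, cfg.group_a.initial_dist,
                                      cfg.group_a.persistence),
                group_b=cfg.group_b,
            )

    def test_persistence_must_stay_below_one(self):
        cfg = uniform_config(n_states=3)
        with pytest.raises(ConfigError, match="persistence"):
            SyntheticConfig(
                states=cfg.states,
                group_a=GroupDynamics(5, cfg.group_a.transition_matrix,
                                      cfg.group_a.initial_dist,
                                      np.array([0.5, 1.0, 0.5])),
                group_b=cfg.group_b,
            )


class TestGenerateStreams:
    def test_same_seed_gives_identical_output(self):
        cfg = harmonious_config(n_full_term=4, n_preterm=3, seed=11)
        assert generate_streams(cfg) == generate_streams(cfg)

    def test_different_seeds_differ(self):
        a = generate_streams(harmonious_config(n_full_term=4, n_preterm=3, seed=1))
        b = generate_streams(harmonious_config(n_full_term=4, n_preterm=3, seed=2))
        assert a != b

    def test_group_sizes_and_labels(self):
        streams = generate_streams(harmonious_config(n_full_term=5, n_preterm=7, seed=0))
        assert sum(s.group == GROUP_A for s in streams) == 5
        assert sum(s.group == GROUP_B for s in streams) == 7
        assert len({s.dyad_id for s in streams}) == 12

    def test_all_streams_validate_cleanly(self, codebook):
        streams = generate_streams(
            harmonious_config(n_full_term=5, n_preterm=5, seed=8, other_rate=0.05)
        )
        assert all(validate_stream(s, codebook) == [] for s in streams)

    def test_other_rate_inserts_other_codes(self):
        streams = generate_streams(
            harmonious_config(n_full_term=10, n_preterm=1, seed=4, other_rate=0.1)
        )
        seconds = sum(len(s) for s in streams)
        others = sum(
            (i == 8) or (m == 10)
            for s in streams
            for i, m in zip(s.infant_codes, s.mother_codes)
        )
        assert 0.05 < others / seconds < 0.15

    def test_dwell_per_visit_matches_geometric_mean(self):
        """Observed mean dwell per visit ~ 1/(1 - persistence)."""
        cfg = uniform_config(n_full_term=1, n_preterm=1, n_states=4, seed=5)
        long_cfg = SyntheticConfig(
            states=cfg.states,
            group_a=cfg.group_a,
            group_b=cfg.group_b,
            length_mean=100_000.0,
            length_sd=0.0,
            length_min=100_000,
        )
        (stream, *_) = generate_streams(long_cfg)
        runs = []
        current = 1
        combined = stream.combined()
        for prev, cur in zip(combined, combined[1:]):
            if cur == prev:
                current += 1
            else:
                runs.append(current)
                current = 1
        runs.append(current)
        persistence = float(cfg.group_a.persistence[0])  # uniform across states
        assert np.mean(runs) == pytest.approx(1 / (1 - persistence), rel=0.05)

    def test_recording_length_model(self):
        """Empirical mean length within 2 s of the Monte-Carlo truncated-normal
        expectation at the default 415 s / SD 118 s setting."""
        cfg = harmonious_config(n_full_term=10_000, n_preterm=1, seed=6)
        lengths = [len(s) for s in generate_streams(cfg) if s.group == GROUP_A]
        oracle_rng = np.random.default_rng(123)
        draws = oracle_rng.normal(415.0, 118.0, size=2_000_000)
        oracle_mean = draws[draws >= 59.5].mean()  # integer rounding boundary
        assert np.mean(lengths) == pytest.approx(oracle_mean, abs=2.0)
        assert min(lengths) >= 60


class TestPlantedDifferences:
    def test_empty_plant_list_is_identity(self):
        cfg = harmonious_config(seed=3)
        assert make_planted_config(cfg, []) is cfg

    def test_planted_rows_remain_stochastic(self):
        cfg = harmonious_config(seed=3)
        edge = Transition.parse("6-15:3-15")
        planted = make_planted_config(cfg, [PlantedDifference(edge, 2.0)])
        m = planted.group_b.transition_matrix
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m >= 0)
        assert np.allclose(np.diag(m), 0.0)

    def test_planted_expected_rate_offset_is_exact(self):
        cfg = harmonious_config(seed=3)
        edge = Transition.parse("6-15:3-15")
        planted = make_planted_config(cfg, [PlantedDifference(edge, 2.0)])
        idx = {s: i for i, s in enumerate(cfg.states)}
        u, v = idx[edge.source], idx[edge.target]
        delta = (
            expected_rates(planted.group_b.transition_matrix)[u, v]
            - expected_rates(planted.group_a.transition_matrix)[u, v]
        )
        assert delta == pytest.approx(2.0, abs=1e-6)

    def test_infeasible_offset_rejected(self):
        cfg = harmonious_config(seed=3)
        edge = Transition.parse("6-15:3-15")
        with pytest.raises(ConfigError, match="[Ii]nfeasible"):
            make_planted_config(cfg, [PlantedDifference(edge, 150.0)])

    def test_unknown_edge_rejected(self):
        cfg = harmonious_config(seed=3)
        with pytest.raises(ConfigError, match="unknown"):
            make_planted_config(
                cfg, [PlantedDifference(Transition.parse("7-17:7-19"), 1.0)]
            )


class TestDynamicsHelpers:
    def test_stationary_distribution_fixed_point(self):
        m = harmonious_config().group_a.transition_matrix
        pi = stationary_distribution(m)
        assert pi.sum() == pytest.approx(1.0)
        assert np.allclose(pi @ m, pi, atol=1e-9)

    def test_expected_rates_sum_to_hundred(self):
        m = harmonious_config().group_a.transition_matrix
        assert expected_rates(m).sum() == pytest.approx(100.0)
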