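"""Synthetic culture generator: determinism, composition, signal model."""

import numpy as np
import pytest
import yaml
from scipy import stats

from sporegate import SynthConfig, ValidationError, simulate_culture
from sporegate.synth import (
    PopulationSpec,
    default_populations,
    simulate_timecourse,
)


class TestSimulateCulture:
    def test_same_seed_bit_identical(self):
        config = SynthConfig(n_events=5000, seed=3)
        a, la, fa = simulate_culture(config)
        b, lb, fb = simulate_culture(config)
        np.testing.assert_array_equal(a.events, b.events)
        np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(fa, fb)

    def test_different_seeds_differ(self):
        a, _, _ = simulate_culture(SynthConfig(n_events=5000, seed=3))
        b, _, _ = simulate_culture(SynthConfig(n_events=5000, seed=4))
        assert not np.array_equal(a.events, b.events)

    def test_label_counts_multinomial(self):
        props = (0.2, 0.3, 0.5)
        n = 100_000
        config = SynthConfig(
            populations=default_populations(props), n_events=n,
            doublet_rate=0.0, seed=8,
        )
        _, labels, _ = simulate_culture(config)
        for lab, p in zip(("vegetative", "endospore", "spore"), props):
            count = np.sum(labels == lab)
            assert abs(count - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_doublet_rate_zero_and_nominal(self):
        _, _, flags0 = simulate_culture(SynthConfig(n_events=4000, doublet_rate=0.0, seed=1))
        assert flags0.sum() == 0
        _, _, flags5 = simulate_culture(SynthConfig(n_events=4000, doublet_rate=0.05, seed=1))
        assert flags5.sum() == 200

    def test_log_means_match_spec_within_three_se(self):
        config = SynthConfig(n_events=30_000, doublet_rate=0.0, seed=13)
        table, labels, _ = simulate_culture(config)
        for spec in config.populations:
            rows = labels == spec.label
            n = rows.sum()
            for ch in table.channel_names:
                observed = np.log(table.channel(ch)[rows]).mean()
                se = spec.log_sds[ch] / np.sqrt(n)
                assert abs(observed - spec.log_means[ch]) < 3 * se, (spec.label, ch)

    def test_asinh_transformed_populations_near_normal(self):
        """Excess kurtosis of asinh(signal) per population is small."""
        config = SynthConfig(n_events=30_000, doublet_rate=0.0, seed=17)
        table, labels, _ = simulate_culture(config)
        for lab in ("vegetative", "endospore", "spore"):
            rows = labels == lab
            for ch in ("SSC-A", "FL1-A"):
                k = stats.kurtosis(np.arcsinh(table.channel(ch)[rows]))
                assert abs(k) < 0.5, (lab, ch)

    def test_doublets_have_inflated_width(self):
        config = SynthConfig(n_events=20_000, seed=23)
        table, _, flags = simulate_culture(config)
        w_singlet = table.channel("SSC-W")[~flags].mean()
        w_doublet = table.channel("SSC-W")[flags].mean()
        assert w_doublet == pytest.approx(config.width_inflation * w_singlet, rel=0.02)


class TestValidation:
    def test_proportions_must_sum_to_one(self):
        pops = default_populations((0.5, 0.2, 0.2))
        with pytest.raises(ValidationError):
            SynthConfig(populations=pops)

    def test_doublet_rate_bounds(self):
        with pytest.raises(ValidationError):
            SynthConfig(doublet_rate=1.0)

    def test_width_inflation_bounds(self):
        with pytest.raises(ValidationError):
            SynthConfig(width_inflation=1.0)

    def test_bad_correlation_matrix(self):
        spec = PopulationSpec(
            label="vegetative", proportion=1.0,
            log_means={"A": 1.0, "B": 1.0, "C": 1.0},
            log_sds={"A": 0.1, "B": 0.1, "C": 0.1},
            channel_correlations={("A", "B"): 0.99, ("A", "C"): 0.99, ("B", "C"): -0.99},
        )
        with pytest.raises(ValidationError):
            spec.covariance(("A", "B", "C"))

    def test_negative_log_sd(self):
        with pytest.raises(ValidationError):
            PopulationSpec(
                label="spore", proportion=1.0,
                log_means={"A": 1.0}, log_sds={"A": -0.1},
            )


class TestTimecourse:
    def test_schedule_shapes_and_metadata(self):
        base = SynthConfig(n_events=2000, seed=4)
        schedule = [(48.0, (0.6, 0.3, 0.1)), (72.0, (0.2, 0.3, 0.5))]
        out = simulate_timecourse(base, schedule)
        assert len(out) == 2
        for (table, labels, _), (t, props) in zip(out, schedule):
            assert table.metadata["time_h"] == t
            assert table.n_events == 2000
            for lab, p in zip(("vegetative", "endospore", "spore"), props):
                assert np.mean(labels == lab) == pytest.approx(p, abs=0.05)

    def test_ramp_truth_counts_increase(self):
        base = SynthConfig(n_events=10_000, doublet_rate=0.0, seed=2)
        schedule = [
            (t, (1 - s, 0.0, s)) for t, s in zip(range(5), (0.1, 0.3, 0.5, 0.7, 0.9))
        ]
        out = simulate_timecourse(base, schedule)
        spores = [np.sum(labels == "spore") for _, labels, _ in out]
        assert all(b > a for a, b in zip(spores, spores[1:]))

    def test_replicates_differ_but_match_proportions(self):
        base = SynthConfig(n_events=10_000, doublet_rate=0.0, seed=6)
        out = simulate_timecourse(base, [(48.0, (0.3, 0.3, 0.4))] * 3)
        tables = [t.events for t, _, _ in out]
        assert not np.array_equal(tables[0], tables[1])
        assert not np.array_equal(tables[1], tables[2])
        for _, labels, _ in out:
            assert np.mean(labels == "spore") == pytest.approx(0.4, abs=0.02)

    def test_rerun_is_deterministic(self):
        base = SynthConfig(n_events=3000, seed=10)
        a = simulate_timecourse(base, [(1.0, (0.3, 0.3, 0.4))])
        b = simulate_timecourse(base, [(1.0, (0.3, 0.3, 0.4))])
        np.testing.assert_array_equal(a[0][0].events, b[0][0].events)

    def test_malformed_schedule(self):
        base = SynthConfig(n_events=100, seed=0)
        with pytest.raises(ValidationError):
            simulate_timecourse(base, [(1.0, (0.5, 0.5))])


class TestYamlConfig:
    def test_from_yaml_roundtrip(self, tmp_path):
        payload = {
            "n_events": 1000,
            "doublet_rate": 0.02,
            "width_inflation": 1.8,
            "seed": 5,
            "proportions": [0.25, 0.25, 0.5],
        }
        path = tmp_path / "synth.yaml"
        path.write_text(yaml.safe_dump(payload))
        config = SynthConfig.from_yaml(path)
        assert config.n_events == 1000
        assert config.doublet_rate == 0.02
        assert config.populations[2].proportion == 0.5
        table, _, _ = simulate_culture(config)
        assert table.n_events == 1000
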