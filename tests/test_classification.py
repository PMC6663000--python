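"""Reference-model fitting, label transfer and population fractions."""

import numpy as np
import pytest

from sporegate import (
    ChannelLookupError,
    EventTable,
    GaussianComponent,
    MappingError,
    MixtureModel,
    ReferenceClassifier,
    SampleSizeError,
    SynthConfig,
    ValidationError,
    assign_labels,
    asinh_transform,
    fit_reference,
    population_fractions,
    simulate_culture,
    timecourse_report,
)
from sporegate.classification import DEFAULT_DIMS, LABELS, _map_labels
from sporegate.synth import default_populations, simulate_timecourse


def toy_classifier(rule="euclidean"):
    """Hand-built classifier with centers at known positions on (SSC, FL1)."""
    centers = [(1.0, 8.0), (4.0, 7.5), (3.0, 2.0)]  # veg, endo, spore
    comps = tuple(
        GaussianComponent(weight=1 / 3, mean=list(c), covariance=np.eye(2) * 0.1)
        for c in centers
    )
    model = MixtureModel(
        g=3, components=comps, log_likelihood=0.0, n_iter=0, converged=True,
        dims=DEFAULT_DIMS,
    )
    return ReferenceClassifier(
        model=model,
        label_map={0: "vegetative", 1: "endospore", 2: "spore"},
        dims=DEFAULT_DIMS,
        assignment_rule=rule,
    )


def truth_centers(table, labels, dims=DEFAULT_DIMS):
    X = table.channels(dims)
    return {lab: X[labels == lab].mean(axis=0) for lab in np.unique(labels)}


class TestFitReference:
    def test_recovers_generator_centers_and_labels(self, gated):
        table, labels, flags = gated
        clf = fit_reference(table, seed=0)
        truth = truth_centers(table.take(~flags), labels[~flags])
        for k, lab in clf.label_map.items():
            fitted = clf.model.means[k]
            assert np.linalg.norm(fitted - truth[lab]) < 0.2, lab

    def test_too_few_events(self, gated):
        table, _, _ = gated
        with pytest.raises(SampleSizeError):
            fit_reference(table.take(np.arange(100)))

    def test_row_permutation_gives_identical_classifier(self, gated):
        table, _, _ = gated
        rng = np.random.default_rng(0)
        shuffled = table.take(rng.permutation(table.n_events))
        a = fit_reference(table, seed=0)
        b = fit_reference(shuffled, seed=0)
        np.testing.assert_allclose(a.model.means, b.model.means, atol=1e-6)
        assert dict(a.label_map) == dict(b.label_map)

    def test_ambiguous_mapping_raises(self):
        comps = tuple(
            GaussianComponent(weight=1 / 3, mean=m, covariance=np.eye(2))
            # the two high-FL1 clusters tie on SSC: endospore call is ambiguous
            for m in ([1.0, 5.0], [1.0, 4.0], [0.0, 1.0])
        )
        model = MixtureModel(
            g=3, components=comps, log_likelihood=0.0, n_iter=0, converged=True,
            dims=DEFAULT_DIMS,
        )
        with pytest.raises(MappingError):
            _map_labels(model, fl1_dim=1, ssc_dim=0)

    def test_low_weight_component_warns(self):
        config = SynthConfig(
            populations=default_populations((0.005, 0.495, 0.5)),
            n_events=20_000, doublet_rate=0.0, seed=3,
        )
        table, _, _ = simulate_culture(config)
        table = asinh_transform(table)
        with pytest.warns(UserWarning, match="subpopulations"):
            fit_reference(table, seed=0)


class TestAssignLabels:
    def test_event_at_center_gets_that_label(self):
        clf = toy_classifier()
        table = EventTable(np.array([[4.0, 7.5]]), DEFAULT_DIMS)
        assert assign_labels(clf, table)[0] == "endospore"

    def test_equidistant_tie_goes_to_lower_index(self):
        clf = toy_classifier()
        midpoint = (np.array([1.0, 8.0]) + np.array([4.0, 7.5])) / 2
        table = EventTable(midpoint.reshape(1, 2), DEFAULT_DIMS)
        assert assign_labels(clf, table)[0] == "vegetative"

    def test_high_agreement_with_generator_truth(self, classifier):
        config = SynthConfig(n_events=10_000, doublet_rate=0.0, seed=77)
        table, labels, _ = simulate_culture(config)
        table = asinh_transform(table)
        assigned = assign_labels(classifier, table)
        assert np.mean(assigned == labels) >= 0.95

    def test_posterior_rule_matches_model_hard_assignments(self, classifier, gated):
        table, _, _ = gated
        assigned = assign_labels(classifier, table, rule="posterior")
        hard = classifier.model.predict(table.channels(classifier.dims))
        expected = np.array([classifier.label_map[k] for k in hard])
        np.testing.assert_array_equal(assigned, expected)

    def test_missing_dims(self, classifier):
        table = EventTable(np.zeros((5, 1)), ("FSC-A",))
        with pytest.raises(ChannelLookupError):
            assign_labels(classifier, table)

    def test_serialization_roundtrip(self, classifier, gated):
        table, _, _ = gated
        back = ReferenceClassifier.from_json(classifier.to_json())
        np.testing.assert_array_equal(
            assign_labels(back, table), assign_labels(classifier, table)
        )


class TestPopulationFractions:
    def test_simple_arithmetic(self):
        out = population_fractions(
            ["spore", "spore", "vegetative", "endospore"], "s"
        )
        assert out.fractions == {"spore": 0.5, "vegetative": 0.25, "endospore": 0.25}
        assert out.n_total == 4

    def test_single_label(self):
        out = population_fractions(["spore"] * 7)
        assert out.fractions["spore"] == 1.0
        assert out.counts["vegetative"] == 0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            population_fractions([])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            population_fractions(["spore", "blob"])

    def test_invariant_to_order_and_duplication(self, rng):
        labels = rng.choice(LABELS, size=300)
        base = population_fractions(labels).fractions
        shuffled = population_fractions(rng.permutation(labels)).fractions
        doubled = population_fractions(np.concatenate([labels, labels])).fractions
        assert base == shuffled == doubled


class TestTimecourse:
    def test_single_sample_matches_population_fractions(self, classifier, gated):
        table, _, _ = gated
        table = table.with_metadata(sample_id="only", strain="X", time_h=48.0)
        df = timecourse_report([table], classifier)
        direct = population_fractions(assign_labels(classifier, table), "only")
        assert len(df) == 1
        for lab in LABELS:
            assert df.loc[0, f"frac_{lab}"] == direct.fractions[lab]

    def test_spore_ramp_is_monotone(self, classifier):
        base = SynthConfig(n_events=20_000, doublet_rate=0.0, seed=5)
        ramp = [0.1, 0.3, 0.5, 0.7, 0.9]
        schedule = [(48 + 12 * i, (0.8 * (1 - s), 0.2 * (1 - s), s))
                    for i, s in enumerate(ramp)]
        samples = simulate_timecourse(base, schedule)
        tables = [asinh_transform(t) for t, _, _ in samples]
        df = timecourse_report(tables, classifier)
        spore = df["frac_spore"].to_numpy()
        assert np.all(np.diff(spore) > 0)
        np.testing.assert_allclose(spore, ramp, atol=0.02)

    def test_replicates_have_small_between_sd(self, classifier):
        base = SynthConfig(n_events=20_000, doublet_rate=0.0, seed=9)
        schedule = [(48.0, (0.3, 0.3, 0.4))] * 3
        samples = simulate_timecourse(base, schedule)
        tables = [asinh_transform(t) for t, _, _ in samples]
        df = timecourse_report(tables, classifier)
        for lab in LABELS:
            assert df[f"frac_{lab}"].std() < 0.02

    def test_fraction_recovery_against_truth(self, classifier):
        config = SynthConfig(
            populations=default_populations((0.2, 0.3, 0.5)),
            n_events=20_000, doublet_rate=0.0, seed=21,
        )
        table, labels, _ = simulate_culture(config)
        df = timecourse_report([asinh_transform(table)], classifier)
        for lab, p in zip(LABELS, (0.2, 0.3, 0.5)):
            assert df.loc[0, f"frac_{lab}"] == pytest.approx(p, abs=0.02)
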