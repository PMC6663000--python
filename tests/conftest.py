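"""Shared fixtures: simulated cultures and prepared (gated) tables."""

import numpy as np
import pytest

from sporegate import (
    SynthConfig,
    asinh_transform,
    exclude_agglomerates,
    fit_reference,
    simulate_culture,
)
from sporegate.synth import PopulationSpec, default_populations


@pytest.fixture(scope="session")
def culture():
    """Balanced 3-population culture with 5% doublets (n=20000, frozen seed)."""
    config = SynthConfig(n_events=20_000, seed=42)
    return simulate_culture(config)


@pytest.fixture(scope="session")
def gated(culture):
    """The culture after asinh transform and singlet gating, with aligned truth."""
    table, labels, flags = culture
    transformed = asinh_transform(table)
    mask = exclude_agglomerates(transformed, seed=0)
    return transformed.take(mask.keep), labels[mask.keep], flags[mask.keep]


@pytest.fixture(scope="session")
def classifier(gated):
    table, _labels, _flags = gated
    return fit_reference(table, seed=0)


def two_population_specs(separation_sds: float = 4.0, fl1_sd: float = 0.22):
    """Vegetative cells + spores 1:1, FL1 log-means `separation_sds` apart.

    Used by the stain-QC tests, which need a controlled two-population
    mixture rather than the full three-population preset.
    """
    veg, _endo, spore = default_populations((0.5, 0.0, 0.5))
    lm_cells = dict(veg.log_means)
    lm_spores = dict(spore.log_means)
    lm_spores["FL1-A"] = lm_cells["FL1-A"] - separation_sds * fl1_sd
    cells = PopulationSpec(
        label="vegetative", proportion=0.5, log_means=lm_cells,
        log_sds=veg.log_sds, channel_correlations=veg.channel_correlations,
    )
    spores = PopulationSpec(
        label="spore", proportion=0.5, log_means=lm_spores,
        log_sds=spore.log_sds, channel_correlations=spore.channel_correlations,
    )
    return (cells, spores)


@pytest.fixture(scope="session")
def stain_mix():
    """1:1 cells/spores mixture at ~4 pooled-SD FL1 separation, with truth."""
    config = SynthConfig(
        populations=two_population_specs(), n_events=30_000, seed=7
    )
    return simulate_culture(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
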