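import numpy as np
import pytest

from stresstiming import ChainSpec, ReporterSpec, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def noiseless_colony():
    """Small noiseless microcolony with homogeneous growth (exact recovery).

    Reporter turnover makes per-area expression relax quickly to its
    plateau, so the threshold crossing trails the latent activation time by
    the constant -ln(0.75)/(g + decay) plus the maturation delay.
    """
    config = SimConfig(
        n_founders=12,
        seed=42,
        growth_rate_mean=0.35,
        growth_rate_sd=0.0,
        division_ratio_sd=0.0,
        pre_stress_duration=0.5,
        post_stress_duration=9.0,
        frame_interval=1 / 6,
        chain=ChainSpec(n_steps=8, mean_time=4.0),
        reporters={"yfp": ReporterSpec(maturation_time=0.0, decay_rate=3.0)},
        randomize_initial_size=False,
        lineage_jitter_sd=0.0,
    )
    table, truth, tree = generate_dataset(config)
    return config, table, truth, tree


@pytest.fixture(scope="session")
def noisy_colony():
    """Colony with growth heterogeneity, noise, bleaching and background."""
    config = SimConfig(
        n_founders=8,
        seed=7,
        growth_rate_mean=0.3,
        growth_rate_sd=0.05,
        division_ratio_sd=0.05,
        pre_stress_duration=1.0,
        post_stress_duration=8.0,
        frame_interval=1 / 6,
        chain=ChainSpec(n_steps=8, mean_time=3.0),
        reporters={
            "yfp": ReporterSpec(
                maturation_time=10 / 60,
                decay_rate=2.0,
                bleach_per_frame=0.03,
                autofluorescence=2.0,
                autofluorescence_trend=0.1,
                noise_sd=0.5,
            )
        },
        background={"yfp": 1.5},
        lineage_jitter_sd=0.05,
    )
    table, truth, tree = generate_dataset(config)
    return config, table, truth, tree
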