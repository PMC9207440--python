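import dataclasses

import numpy as np
import pytest

from rhythmq.simulate import (
    DesignGrid,
    GeneTruth,
    QpcrNoiseModel,
    ScenarioConfig,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def design_times():
    """The study sampling grid: every 4 h plus the next-day 27-h follow-up."""
    return np.array([3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0])


def make_scenario(
    genes,
    *,
    seed=0,
    n_per_time=7,
    groups=("LD_scheduled",),
    tissues=("liver",),
    output_kind="ct",
    noise_scale="log2",
    ref_sd=0.0,
    technical_sd=0.0,
):
    """Single-group scenario builder used across the test modules."""
    light = {g: ("DD" if g.startswith("DD") else "LD") for g in groups}
    feeding = {g: ("random" if "random" in g else "scheduled") for g in groups}
    design = DesignGrid(
        groups=tuple(groups),
        n_per_time=n_per_time,
        tissues=tuple(tissues),
        light_regime=light,
        feeding_regime=feeding,
    )
    return ScenarioConfig(
        design=design,
        genes=list(genes),
        noise=QpcrNoiseModel(ref_sd=ref_sd, technical_sd=technical_sd),
        seed=seed,
        output_kind=output_kind,
        noise_scale=noise_scale,
    )


@pytest.fixture
def zero_noise_table():
    """Noise-free duplicate-well Ct table for one rhythmic and one flat gene."""
    sc = make_scenario(
        [
            GeneTruth(gene="per1a", mesor=5.0, amplitude=2.0, acrophase_h=17.5),
            GeneTruth(gene="clock1a", mesor=2.0),
        ]
    )
    return generate_dataset(sc), sc


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
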