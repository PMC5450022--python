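import numpy as np
import pytest

from emtconv import morphology
from emtconv.config import RunConfig
from emtconv.pipeline import analyze_movie
from emtconv.synthetic.movie import (
    ConversionRule,
    MovieConfig,
    generate_movie,
)


@pytest.fixture(scope="session")
def demo_movie():
    """The shipped demo conditions: seeded movie with >=300 final cells,
    MEFs converting in scheduled waves."""
    cfg = MovieConfig(seed=11)
    labels, nuclei, truth = generate_movie(cfg)
    return cfg, labels, nuclei, truth


@pytest.fixture(scope="session")
def demo_analysis(demo_movie):
    cfg, labels, nuclei, truth = demo_movie
    rc = RunConfig(seed=cfg.seed)
    return analyze_movie(labels, nuclei, rc, truth,
                         motion_step_sd=max(cfg.motion_step_sd.values()))


def recovery_config(seed: int) -> MovieConfig:
    """Mixed-archetype conditions without scheduled conversions, used to
    recover the generator's division and motion parameters from tracked
    data."""
    return MovieConfig(
        seed=seed,
        n_frames=30,
        n_initial_cells=120,
        field_size=(2100, 2100),
        archetype_mix={
            morphology.MEF_LIKE: 0.5,
            morphology.NEURON_LIKE: 0.3,
            morphology.SHRUNKEN: 0.2,
        },
        division_prob={
            morphology.MEF_LIKE: 0.06,
            morphology.NEURON_LIKE: 0.04,
            morphology.SHRUNKEN: 0.0,
        },
        apoptosis_prob={
            morphology.MEF_LIKE: 0.0,
            morphology.NEURON_LIKE: 0.0,
            morphology.SHRUNKEN: 0.0,
        },
        conversion_schedule=[],
    )


RECOVERY_SEEDS = (5, 6, 7)


@pytest.fixture(scope="session")
def recovery_movie():
    """First replicate of the recovery conditions (single-movie checks)."""
    cfg = recovery_config(RECOVERY_SEEDS[0])
    labels, nuclei, truth = generate_movie(cfg)
    return cfg, labels, nuclei, truth


@pytest.fixture(scope="session")
def recovery_analysis(recovery_movie):
    cfg, labels, nuclei, truth = recovery_movie
    rc = RunConfig(seed=cfg.seed)
    return analyze_movie(labels, nuclei, rc, truth,
                         motion_step_sd=max(cfg.motion_step_sd.values()))


@pytest.fixture(scope="session")
def recovery_replicates(recovery_movie, recovery_analysis):
    """Three seeded replicates of the recovery conditions, analyzed;
    pooled for parameter-recovery checks."""
    out = [(recovery_movie[0], recovery_movie[3], recovery_analysis)]
    for seed in RECOVERY_SEEDS[1:]:
        cfg = recovery_config(seed)
        labels, nuclei, truth = generate_movie(cfg)
        res = analyze_movie(labels, nuclei, RunConfig(seed=seed), truth,
                            motion_step_sd=max(cfg.motion_step_sd.values()))
        out.append((cfg, truth, res))
    return out


def single_cell_config(**kw) -> MovieConfig:
    """One MEF-like cell, no events, small field."""
    base = dict(
        n_frames=3,
        n_initial_cells=1,
        field_size=(220, 220),
        division_prob={k: 0.0 for k in morphology.CLASSES[:3]},
        apoptosis_prob={k: 0.0 for k in morphology.CLASSES[:3]},
        motion_step_sd={k: 0.0 for k in morphology.CLASSES[:3]},
        conversion_schedule=[],
        seed=7,
    )
    base.update(kw)
    return MovieConfig(**base)
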