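import numpy as np
import pytest

from accumaint.design import ExperimentDesign
from accumaint.synthetic_data import (
    CorpusSpec,
    GenParamsDDM,
    HierBehaviorParams,
    PlantedAssociation,
    generate_meta_corpus,
    simulate_hier_behavior,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_design():
    """A compact design for fast fits: 6 subjects, 2 RT runs."""
    return ExperimentDesign(n_subjects=6, trials_per_run=80, runs=("RT", "DR", "RT"))


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def behavior_trials(small_design):
    """Hierarchically generated RT-condition trials, 40 trials/cell."""
    return simulate_hier_behavior(
        small_design, HierBehaviorParams(), seed=101, condition="RT", trials_per_level=40
    )


def flat_ddm_params(v=1.0, a=2.0, t_nd=0.3, sv=0.0, st=0.0):
    """Same drift/boundary at every coherence level."""
    return GenParamsDDM(
        drift_per_level={l: v for l in (1, 2, 3, 4)},
        boundary_per_level={l: a for l in (1, 2, 3, 4)},
        t_nd=t_nd,
        sv=sv,
        st=st,
    )


@pytest.fixture(scope="session")
def toy_corpus():
    """300-article corpus with one planted term-region association."""
    planted = PlantedAssociation(
        term="decision", center_mm=(10.0, 10.0, 10.0), p_activation_given_term=0.8, base_rate=0.1
    )
    spec = CorpusSpec(
        n_articles=300,
        planted=(planted,),
        brain_box_mm=((-30.0, 50.0), (-30.0, 50.0), (-30.0, 50.0)),
    )
    terms, foci, planted_map = generate_meta_corpus(spec, seed=7)
    return spec, terms, foci, planted_map
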