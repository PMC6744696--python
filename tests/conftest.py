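"""Shared fixtures.

The expensive fixture is ``desk_run``: one full desk-scale end-to-end
training of the regression network on a seeded synthetic corpus (150
train / 30 validation / 30 test tiles of 64x64).  It is session-scoped and
shared by the end-to-end tests so the suite trains only once.
"""

import pytest

from micronet.evaluation import match, pooled_metrics, select_xi
from micronet.inference import detect, predict_batch
from micronet.model import NetworkSpec, build_network
from micronet.synthetic import SynthStyle, generate_dataset
from micronet.training import DataSource, desk_profile, train

DESK_SEED = 2024


@pytest.fixture(scope="session")
def desk_corpus():
    """210 seeded 64x64 tiles in the default style: 150/30/30 split."""
    samples = generate_dataset(SynthStyle(), 210, 64, 64, seed=DESK_SEED)
    return dict(train=samples[:150], val=samples[150:180], test=samples[180:210])


@pytest.fixture(scope="session")
def desk_run(desk_corpus):
    """Train the desk-scale network once and evaluate it on held-out tiles."""
    config = desk_profile(seed=DESK_SEED)
    network = build_network(NetworkSpec(base_width=8), seed=DESK_SEED)
    network, history = train(
        network,
        DataSource(desk_corpus["train"]),
        config=config,
        validation=desk_corpus["val"],
    )
    xi = select_xi(network, desk_corpus["val"], config.xi_grid)
    test = desk_corpus["test"]
    maps = predict_batch(network, [s.image for s in test])
    reports = [
        match(detect(m, xi, config.min_distance), s.centers) for m, s in zip(maps, test)
    ]
    return dict(
        network=network,
        config=config,
        history=history,
        xi=xi,
        corpus=desk_corpus,
        test_maps=maps,
        test_reports=reports,
        test_metrics=pooled_metrics(reports),
    )


@pytest.fixture
def tiny_spec():
    """A network small enough for sub-second forward/backward in unit tests."""
    return NetworkSpec(base_width=4, depth=2, dropout_rate=0.0)
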