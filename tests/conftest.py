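import pytest

from ancdnet import (
    Allocation,
    CaseNetwork,
    ConstraintBounds,
    ObjectiveParams,
    Receptor,
    SubstrateSource,
    SynthSpec,
    generate_network,
    load_baseline,
)


@pytest.fixture(scope="session")
def baseline() -> CaseNetwork:
    """The bundled Besòs river-basin case study."""
    return load_baseline()


@pytest.fixture()
def tiny_factory():
    """Small seeded synthetic instances with an exhaustible search space."""

    def make(seed: int, quantum: float = 10000.0) -> CaseNetwork:
        return generate_network(
            SynthSpec(n_sludge=3, n_industrial=2, n_receptors=1, seed=seed),
            params=ObjectiveParams(quantum=quantum),
        )

    return make


@pytest.fixture()
def permissive_bounds() -> ConstraintBounds:
    """Bounds wide enough that any sludge-like blend is feasible."""
    return ConstraintBounds(cn_min=1.0, cn_max=1e6, alk_min=0.1, alk_max=1e9, tox_max=1e6)


def make_source(sid="W1", **kw) -> SubstrateSource:
    defaults = dict(
        kind="sludge",
        daily_volume=10000.0,
        cod=20000.0,
        cn_ratio=30.0,
        alkalinity=3000.0,
        toxicity=1.0,
        distance_km={"R1": 10.0},
    )
    defaults.update(kw)
    return SubstrateSource(id=sid, **defaults)


def make_receptor(rid="R1", **kw) -> Receptor:
    defaults = dict(
        max_external_volume=100000.0,
        own_cod=19000.0,
        own_cn=19.0,
        own_alk=3000.0,
        own_tox=1.5,
    )
    defaults.update(kw)
    return Receptor(id=rid, **defaults)


@pytest.fixture()
def two_source_net(permissive_bounds) -> CaseNetwork:
    """Two sludge-like sources, one receptor, permissive blend bounds."""
    return CaseNetwork(
        sources=[
            make_source("A", daily_volume=3000.0),
            make_source("B", daily_volume=2000.0, cn_ratio=40.0),
        ],
        receptors=[make_receptor(max_external_volume=4000.0)],
        bounds=permissive_bounds,
        params=ObjectiveParams(quantum=1000.0),
    )


@pytest.fixture()
def empty_allocation() -> Allocation:
    return Allocation({})
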