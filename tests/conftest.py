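import pytest

from mitocompare import (
    MitogenomeSpec,
    generate_mitogenome,
    gryllidea_arrangement,
    insect_typical,
)


@pytest.fixture(scope="session")
def ref_order():
    return insect_typical


@pytest.fixture(scope="session")
def type_orders():
    """The four cricket arrangement types as full 37-gene orders."""
    return {t: gryllidea_arrangement(t) for t in ("I", "II", "III", "IVG")}


@pytest.fixture(scope="session")
def analytic_cohort(type_orders):
    """The 38-genome cohort reconstructed from the per-type species counts
    (7 Type I, 23 Type II, 7 Type III, 1 Type IVG)."""
    cohort = []
    for t, n in (("I", 7), ("II", 23), ("III", 7), ("IVG", 1)):
        for k in range(n):
            cohort.append(type_orders[t].rotated(0, label=f"{t}-{k}"))
    return cohort


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic synthetic mitogenome in the typical arrangement."""
    return generate_mitogenome(MitogenomeSpec(seed=11))


@pytest.fixture(scope="session")
def sim_genome_ii():
    return generate_mitogenome(MitogenomeSpec(seed=12, gene_order="II"))
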