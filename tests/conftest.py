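import pytest

from famscape.simulate import FamilySimSpec, PlantedEvent, simulate_family

SMALL_EVENTS = (
    PlantedEvent(column=60, phase=1),
    PlantedEvent(column=90, phase=0, carrier_groups=("A", "B", "C")),
    PlantedEvent(column=150, phase=2, carrier_groups=("D", "E")),
    PlantedEvent(column=200, phase=1, carrier_groups=("A", "D", "F")),
    PlantedEvent(column=260, phase=0),
)


@pytest.fixture(scope="session")
def small_spec():
    return FamilySimSpec(
        n_family_genes=24,
        n_decoy_proteins=30,
        group_labels=tuple("ABCDEF"),
        planted_events=SMALL_EVENTS,
        intronless_fraction=0.25,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """24-gene family over 6 groups with 5 planted events, 25% intronless."""
    return simulate_family(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    """The same bundle serialized to FASTA/GFF3/TSV files."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write(outdir)
    return paths
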