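import pytest

from isomirkit.fixtures import FixtureSpec, make_reference, simulate_reads
from isomirkit.profiler import profile_reads
from isomirkit.tables import RepeatAnnotation, build_tables


@pytest.fixture(scope="session")
def fixture_ref():
    """The default seeded synthetic reference (genome, annotations, truth)."""
    return make_reference(FixtureSpec())


@pytest.fixture(scope="session")
def bundle(fixture_ref):
    """Lookup tables built once for the whole session."""
    return build_tables(
        fixture_ref.genome,
        fixture_ref.precursors,
        "miRCarta",
        RepeatAnnotation(fixture_ref.repeat_rows),
        fixture_ref.variants,
        flank=fixture_ref.spec.flank,
        genome_tag="synthetic-mini",
    )


@pytest.fixture(scope="session")
def sim(fixture_ref, tmp_path_factory):
    """Simulated FASTQ plus its per-read truth."""
    path = tmp_path_factory.mktemp("reads") / "reads.fastq"
    truth = simulate_reads(fixture_ref, path)
    return path, truth


@pytest.fixture(scope="session")
def profiled(bundle, sim):
    """Quantified hits, frequency table and run summary for the simulated reads."""
    path, _ = sim
    return profile_reads(bundle, path)
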