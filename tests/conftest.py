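import pytest
from hypothesis import settings

import seedbin as sb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_reads(seqs, prefix="r"):
    return sb.ReadSet(
        sb.Read(id=f"{prefix}{i}", seq=s) for i, s in enumerate(seqs)
    )


@pytest.fixture(scope="session")
def two_species_sim():
    """Error-free two-species sample: divergent composition, 1000 x 80 bp
    reads at 1:1 abundance on 8 kb genomes."""
    sp1, sp2 = sb.divergent_species_pair(8000, rng=0)
    spec = sb.SimulationSpec(
        species=[sp1, sp2], read_length=80, n_reads=1000,
        error_rate=0.0, rng_seed=0,
    )
    reads, genomes = sb.simulate(spec)
    return reads, genomes


@pytest.fixture(scope="session")
def fitted_binner(two_species_sim):
    reads, _ = two_species_sim
    return sb.TwoPhaseBinner(n_clusters=2, random_state=0).fit(reads)
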