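import numpy as np
import pytest

from hifimag import synthio
from hifimag.taxonomy import default_taxon_path


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mini_community(seed: int = 11) -> synthio.CommunitySpec:
    """Three-chromosome community for fast pipeline-level tests."""
    replicons = tuple(
        synthio.RepliconSpec(
            id=f"chr{i + 1:02d}",
            length_bp=1_000_000,
            topology="circular",
            replicon_class="chromosome",
            gc_fraction=0.45 + 0.05 * i,
            rrn_operon_copies=[3, 1, 2][i],
            trna_types=("Ala", "Gly", "Leu"),
            taxon_path=default_taxon_path(i),
        )
        for i in range(3)
    )
    return synthio.CommunitySpec(replicons, (0.7, 0.2, 0.1), seed=seed)


@pytest.fixture(scope="session")
def mini_fixture_dir(tmp_path_factory):
    """On-disk synthetic fixture shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("minifix")
    synthio.write_fixture(
        out, seed=11, depth_target=2.0, community=mini_community(11),
        tangle_replicon=None,
    )
    return out


@pytest.fixture(scope="session")
def single_replicon_reads():
    """Reads simulated from one 1 Mb replicon at 12x, with truth."""
    spec = synthio.RepliconSpec(
        "chrA", 1_000_000, "circular", "chromosome", 0.5, 2,
        ("Ala", "Gly"), default_taxon_path(0),
    )
    comm = synthio.CommunitySpec((spec,), (1.0,), seed=4)
    reads, truth = synthio.simulate_hifi_reads(
        comm, synthio.ReadModel(), 12.0, 4
    )
    return reads, truth
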