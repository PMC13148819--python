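import numpy as np
import pytest

from pamdesign.fixtures import FixtureParams, default_toy_complex, gen_toy_complex


@pytest.fixture(scope="session")
def toy():
    """The default deterministic protein-DNA toy complex (read-only)."""
    return default_toy_complex()


@pytest.fixture(scope="session")
def small_toy():
    """A smaller complex for O(N^2) brute-force comparisons."""
    return gen_toy_complex(
        FixtureParams(
            dna_sequence="GATTGGGTAC",
            pam_offset=2,
            peptide_sequence="KETNKR",
            peptide_numbers=None,
        )
    )


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory, toy):
    from pamdesign.structure import write_pdb

    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    write_pdb(toy, path)
    return path
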