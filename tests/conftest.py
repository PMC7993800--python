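import numpy as np
import pytest

from fvkit.fixtures import FixtureSpec, _build_backbone, make_fixture_antibody, make_fixture_corpus
from fvkit.foldtree import Chain
from fvkit.regions import ChainKind, ResidueID
from fvkit.structure import Residue, read_chothia_structure, truncate_fv


@pytest.fixture(scope="session")
def clean_entry():
    """PDB text + summary for a defect-free two-chain antibody."""
    return make_fixture_antibody(FixtureSpec(seed=7, pdb_id="ab01"))


@pytest.fixture(scope="session")
def clean_structure(clean_entry):
    text, summary = clean_entry
    return truncate_fv(read_chothia_structure(text, summary))


@pytest.fixture(scope="session")
def nanobody_structure():
    text, summary = make_fixture_antibody(
        FixtureSpec(seed=9, pdb_id="nb01", chains=(ChainKind.HEAVY,))
    )
    return truncate_fv(read_chothia_structure(text, summary))


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """Five clean fixtures plus one duplicate and one low-resolution entry."""
    from fvkit.fixtures import BadResolution

    out = tmp_path_factory.mktemp("corpus")
    make_fixture_corpus(
        7,
        seed=11,
        out_dir=out,
        duplicate_of={5: 0},
        defects={6: (BadResolution(3.2),)},
    )
    return out


def make_chain(chain_id: str, n: int, seed: int, origin=(0.0, 0.0, 0.0)) -> Chain:
    """Small generic peptide chain for kinematics tests."""
    rng = np.random.default_rng(seed)
    residues = [
        Residue(ResidueID(ChainKind.ANTIGEN, i + 1), "A", "ALA", atoms=[])
        for i in range(n)
    ]
    _build_backbone(residues, rng, np.asarray(origin, dtype=float))
    return Chain(chain_id, residues)
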