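import pytest

from enznet.chem import Molecule
from enznet.fixtures import FixtureSpec, generate_superfamily, worked_examples
from enznet.reactions import Directionality, parse_reaction_smiles

# small-molecule corpus used for round-trip and fingerprint-oracle tests
CORPUS_SMILES = [
    "O",
    "C",
    "CO",
    "CCO",
    "CCS",
    "C=C",
    "C#N",
    "CC(C)O",
    "CC(=O)O",
    "OC(=O)CO",
    "OCC(O)CO",
    "C1CCCCC1",
    "c1ccccc1",
    "Cc1ccccc1",
    "OC(=O)c1ccccc1",
    "OC(=O)[C@@H](O)c1ccccc1",
    "OC(=O)C=CC=CC(=O)O",
    "N",
    "CCl",
    "CC(N)C(=O)O",
    "O=C=O",
    "O=C1CCC(C)O1",
    "[NH4+]",
    "CC(=O)[O-]",
]


@pytest.fixture(scope="session")
def corpus():
    return [Molecule.from_smiles(s, identifier=f"m{i}") for i, s in enumerate(CORPUS_SMILES)]


@pytest.fixture(scope="session")
def small_reactions():
    """Hand-written balanced reactions with at most 8 heavy atoms per side."""
    rows = [
        ("r_identity", "CCO>>CCO"),
        ("r_dehydr", "CCO>>C=C.O"),
        ("r_hydr", "C=C.O>>CCO"),
        ("r_racem", "OC(=O)[C@@H](O)C>>OC(=O)[C@H](O)C"),
        ("r_taut", "OC(O)=CC>>OC(=O)CC"),
        ("r_decarb", "OC(=O)C(O)C>>OCC.O=C=O"),
        ("r_deam", "NC(C)C>>C=CC.N"),
        ("r_dehal", "ClCCC>>C=CC.Cl"),
        ("r_lact", "OC(=O)CCCO>>O=C1CCCO1.O"),
        ("r_enediol", "OCC=O>>OC=CO"),
        ("r_ring", "OC(=O)C=CC=C>>O=C1C=CC(C)O1"),
        ("r_ester", "CO.OC(C)=O>>COC(C)=O.O"),
        ("r_amide", "CN.OC(C)=O>>CNC(C)=O.O"),
        ("r_isom", "CC=CC>>C=CCC"),
        ("r_keto", "OCC=C>>CCC=O"),
        ("r_nitrile", "CC#N.O>>CC(N)=O"),
    ]
    return [
        parse_reaction_smiles(s, reaction_id=rid, directionality=Directionality.FORWARD)
        for rid, s in rows
    ]


@pytest.fixture(scope="session")
def bundle():
    """A moderate synthetic superfamily shared across tests."""
    return generate_superfamily(FixtureSpec(n_subgroups=4, families_per_subgroup=6, seed=11))


@pytest.fixture(scope="session")
def examples():
    return worked_examples()
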