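import pytest
from hypothesis import settings, HealthCheck

from biodesc.seqio import random_sequences

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protein_seqs():
    """Seeded random proteins of assorted lengths for property checks."""
    out = []
    for i, length in enumerate((35, 40, 50, 60, 80)):
        out.extend(random_sequences("protein", 2, length, seed=100 + i))
    return out


@pytest.fixture(scope="session")
def dna_seqs():
    out = []
    for i, length in enumerate((20, 30, 40, 50)):
        out.extend(random_sequences("dna", 2, length, seed=200 + i))
    return out


#: small molecules exercising rings, heteroatoms, charges and halogens
FIXTURE_SMILES = [
    "C",                        # methane
    "CC",                       # ethane
    "CCCC",                     # n-butane
    "CC(C)C",                   # isobutane
    "CCO",                      # ethanol
    "CC(=O)O",                  # acetic acid
    "c1ccccc1",                 # benzene
    "c1ccncc1",                 # pyridine
    "CC(=O)Oc1ccccc1C(=O)O",    # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
    "C1CCCCC1",                 # cyclohexane
    "C1CCOC1",                  # THF
    "CCN(CC)CC",                # triethylamine
    "CS(=O)(=O)O",              # methanesulfonic acid
    "Clc1ccc(Cl)cc1",           # dichlorobenzene
    "OCC(O)CO",                 # glycerol
    "N#Cc1ccccc1",              # benzonitrile
    "CC(N)C(=O)O",              # alanine
    "FC(F)(F)c1ccccc1",         # trifluorotoluene
    "O=C1CCCCC1",               # cyclohexanone
]


@pytest.fixture(scope="session")
def fixture_mols():
    from biodesc.chem import parse_structure

    return [parse_structure(s) for s in FIXTURE_SMILES]
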