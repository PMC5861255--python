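"""Chemical parsing, standardization and descriptor-group checks."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem

from biodesc.chem import (
    DESCRIPTOR_GROUPS,
    MoleculeGraph,
    ParseError,
    StandardizationOptions,
    all_descriptors,
    descriptor_group,
    parse_structure,
    standardize_structure,
)
from biodesc.chem.elements import atom_weight


class TestParse:
    def test_methane(self):
        m = parse_structure("C")
        assert m.num_heavy_atoms == 1
        assert len(m.bonds) == 0

    def test_butane(self):
        m = parse_structure("CCCC")
        assert m.num_heavy_atoms == 4
        assert len(m.bonds) == 3
        assert all(b.order == 1.0 for b in m.bonds)

    def test_benzene_aromatic_perception(self):
        m = parse_structure("c1ccccc1")
        assert m.num_heavy_atoms == 6
        assert all(a.aromatic for a in m.atoms)
        assert all(b.order == 1.5 for b in m.bonds)

    def test_unparseable_raises_with_input(self):
        with pytest.raises(ParseError, match="not_a_smiles"):
            parse_structure("not_a_smiles")

    def test_empty_raises(self):
        with pytest.raises(ParseError):
            parse_structure("   ")

    def test_inchi(self):
        m = parse_structure("InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", "inchi")
        assert m.num_heavy_atoms == 3

    def test_sdf_first_record(self):
        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CCO")) + "\n$$$$\n"
        block += Chem.MolToMolBlock(Chem.MolFromSmiles("CC")) + "\n$$$$\n"
        m = parse_structure(block, "sdf")
        assert m.num_heavy_atoms == 3


class TestStandardize:
    def test_salt_strip_and_neutralize(self):
        m = parse_structure("CC(=O)[O-].[Na+]")
        out = standardize_structure(m)
        assert out.num_heavy_atoms == 4
        assert out.to_smiles() == "CC(=O)O"

    def test_ethanol_fixed_point(self):
        m = parse_structure("CCO")
        assert standardize_structure(m).to_smiles() == "CCO"

    def test_idempotent_on_fixture_molecules(self, fixture_mols):
        for m in fixture_mols:
            once = standardize_structure(m)
            twice = standardize_structure(once)
            assert once.to_smiles() == twice.to_smiles()

    def test_validation_flags(self):
        m = parse_structure("CC(=O)[O-].[Na+]")
        # validate only, nothing else applied: fragments and charges flagged
        import dataclasses

        opts = dataclasses.replace(StandardizationOptions.none(), validate=True)
        out = standardize_structure(m, opts)
        assert "multiple_fragments" in out.validation_flags
        assert "net_or_local_charges" in out.validation_flags

    def test_stereo_stripped(self):
        out = standardize_structure(parse_structure("C[C@H](N)C(=O)O"))
        assert "@" not in out.to_smiles()


class TestDescriptorDimensions:
    def test_group_dimensions_on_fixtures(self, fixture_mols):
        for m in fixture_mols:
            for group, (_, dim) in DESCRIPTOR_GROUPS.items():
                assert len(descriptor_group(m, group)) == dim, group

    def test_total_775(self, fixture_mols):
        for m in fixture_mols[:5]:
            v = all_descriptors(m)
            assert len(v) == 775
            assert len(set(v.names)) == 775
            assert np.isfinite(v.values).all()

    def test_total_equals_sum_of_groups(self, fixture_mols):
        m = fixture_mols[4]
        total = sum(
            len(descriptor_group(m, g)) for g in DESCRIPTOR_GROUPS
        )
        assert len(all_descriptors(m)) == total == 775

    def test_unknown_group_raises(self, fixture_mols):
        with pytest.raises(ValueError, match="available"):
            descriptor_group(fixture_mols[0], "nope")

    def test_determinism(self, fixture_mols):
        assert all_descriptors(fixture_mols[8]) == all_descriptors(
            fixture_mols[8]
        )


class TestGraphIsomorphismInvariance:
    @pytest.mark.parametrize(
        "smi_a,smi_b",
        [
            ("OCC", "CCO"),
            ("c1ccccc1C", "Cc1ccccc1"),
            ("C(C)(C)C", "CC(C)C"),
        ],
    )
    def test_same_molecule_same_vector(self, smi_a, smi_b):
        va = all_descriptors(parse_structure(smi_a))
        vb = all_descriptors(parse_structure(smi_b))
        assert np.allclose(va.values, vb.values)


def _heavy_graph(mol):
    """Adjacency list + distance matrix by explicit BFS (test oracle)."""
    n = mol.GetNumAtoms()
    adj = {i: [] for i in range(n)}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    dist = [[math.inf] * n for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s][v] is math.inf:
                        dist[s][v] = dist[s][u] + 1
                        nxt.append(v)
            frontier = nxt
    return adj, dist


class TestTopologicalOracles:
    def test_wiener_butane(self):
        v = descriptor_group(parse_structure("CCCC"), "topology")
        assert v["topology.W"] == 10.0

    def test_kappa1_butane(self):
        v = descriptor_group(parse_structure("CCCC"), "kappa")
        assert v["kappa.kappa1"] == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "smi", ["CCCC", "CC(C)C", "C1CCCCC1", "CCO", "CC(=O)O", "c1ccccc1"]
    )
    def test_wiener_and_zagreb_brute_force(self, smi):
        mol = parse_structure(smi).mol
        adj, dist = _heavy_graph(mol)
        n = mol.GetNumAtoms()
        wiener = sum(
            dist[i][j] for i in range(n) for j in range(i + 1, n)
        )
        zm1 = sum(len(adj[i]) ** 2 for i in range(n))
        zm2 = sum(
            len(adj[b.GetBeginAtomIdx()]) * len(adj[b.GetEndAtomIdx()])
            for b in mol.GetBonds()
        )
        v = descriptor_group(mol, "topology")
        assert v["topology.W"] == pytest.approx(wiener)
        assert v["topology.ZM1"] == pytest.approx(zm1)
        assert v["topology.ZM2"] == pytest.approx(zm2)

    @pytest.mark.parametrize("smi", ["CCCC", "CC(C)C", "CCO", "CC(C)(C)C"])
    def test_chi_low_orders_brute_force(self, smi):
        mol = parse_structure(smi).mol
        adj, dist = _heavy_graph(mol)
        n = mol.GetNumAtoms()
        deg = {i: len(adj[i]) for i in range(n)}
        chi0 = sum(1 / math.sqrt(deg[i]) for i in range(n))
        chi1 = sum(
            1 / math.sqrt(deg[b.GetBeginAtomIdx()] * deg[b.GetEndAtomIdx()])
            for b in mol.GetBonds()
        )
        # order-2 paths by enumeration i-j-k, i<k
        chi2 = 0.0
        for j in range(n):
            for i, k in itertools.combinations(adj[j], 2):
                chi2 += 1 / math.sqrt(deg[i] * deg[j] * deg[k])
        v = descriptor_group(mol, "connectivity")
        assert v["connectivity.Chi0"] == pytest.approx(chi0)
        assert v["connectivity.Chi1"] == pytest.approx(chi1)
        assert v["connectivity.Chi2"] == pytest.approx(chi2)

    @pytest.mark.parametrize("smi", ["CCCC", "CC(C)C", "CC(C)(C)CC"])
    def test_kappa_formulas_brute_force(self, smi):
        mol = parse_structure(smi).mol
        adj, dist = _heavy_graph(mol)
        n = mol.GetNumAtoms()
        p1 = mol.GetNumBonds()
        p2 = sum(
            1
            for j in range(n)
            for _ in itertools.combinations(adj[j], 2)
        )
        v = descriptor_group(mol, "kappa")
        assert v["kappa.kappa1"] == pytest.approx(n * (n - 1) ** 2 / p1**2)
        assert v["kappa.kappa2"] == pytest.approx(
            (n - 1) * (n - 2) ** 2 / p2**2
        )


class TestAutocorrelationOracle:
    @pytest.mark.parametrize("kind,group", [
        ("moreau_broto", "autocorrelation_mb"),
        ("moran", "autocorrelation_moran"),
        ("geary", "autocorrelation_geary"),
    ])
    def test_double_loop_oracle(self, kind, group):
        mol = parse_structure("CCOC(=O)N").mol  # mixed elements
        _, dist = _heavy_graph(mol)
        n = mol.GetNumAtoms()
        for scheme in ("mass", "electronegativity"):
            w = [atom_weight(a.GetAtomicNum(), scheme) for a in mol.GetAtoms()]
            wbar = sum(w) / n
            ss = sum((x - wbar) ** 2 for x in w)
            v = descriptor_group(mol, group)
            for d in range(1, 9):
                pairs = [
                    (i, j)
                    for i in range(n)
                    for j in range(i + 1, n)
                    if dist[i][j] == d
                ]
                if not pairs:
                    expect = 0.0
                elif kind == "moreau_broto":
                    expect = sum(w[i] * w[j] for i, j in pairs)
                elif kind == "moran":
                    num = sum(
                        (w[i] - wbar) * (w[j] - wbar) for i, j in pairs
                    ) / len(pairs)
                    expect = num / (ss / n) if ss else 0.0
                else:
                    num = sum((w[i] - w[j]) ** 2 for i, j in pairs) / (
                        2 * len(pairs)
                    )
                    expect = num / (ss / (n - 1)) if ss else 0.0
                assert v[f"{kind}.{scheme}.d{d}"] == pytest.approx(
                    expect, abs=1e-10
                )


class TestDegenerateInputs:
    def test_single_atom_all_finite(self):
        v = all_descriptors(parse_structure("C"))
        assert np.isfinite(v.values).all()

    def test_single_atom_topology_sentinel(self):
        v = descriptor_group(parse_structure("[He]"), "topology")
        assert np.allclose(v.values, 0.0)
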