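"""Protein descriptor families against direct-loop oracles and identities."""

import itertools

import numpy as np
import pytest

from biodesc import protein
from biodesc.seqio import AMINO_ACIDS, random_sequences
from biodesc.tables import (
    default_distance_matrices,
    load_aa_property,
    load_ctd_groupings,
)

TOL = 1e-10


class TestPeptideComposition:
    def test_single_letter_sequence(self):
        v = protein.peptide_composition("MM", k=1)
        assert v["M"] == 1.0
        assert sum(val for n, val in v if n != "M") == 0.0

    def test_dipeptide_direct_count(self):
        v = protein.peptide_composition("MKM", k=2)
        assert v["MK"] == pytest.approx(0.5)
        assert v["KM"] == pytest.approx(0.5)
        assert v.values.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("k,dim", [(1, 20), (2, 400), (3, 8000)])
    def test_dimensions(self, k, dim, protein_seqs):
        assert len(protein.peptide_composition(protein_seqs[0], k)) == dim

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_sums_to_one(self, k, protein_seqs):
        for seq in protein_seqs:
            v = protein.peptide_composition(seq, k)
            assert v.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            protein.peptide_composition("MK", k=3)


class TestAutocorrelation:
    def test_default_dimension_240(self, protein_seqs):
        seq = protein_seqs[-1]
        for kind in ("moreau_broto", "moran", "geary"):
            assert len(protein.autocorrelation(seq, kind)) == 240

    def test_homopolymer_moran_zero(self):
        v = protein.autocorrelation("A" * 40, "moran", maxlag=5)
        assert np.allclose(v.values, 0.0)

    @pytest.mark.parametrize("kind", ["moreau_broto", "moran", "geary"])
    def test_matches_brute_force_loop(self, kind):
        seq = random_sequences("protein", 1, 35, seed=42)[0]
        prop = load_aa_property("hydrophobicity")
        v = protein.autocorrelation(seq, kind, [prop], maxlag=3)
        p = [prop[a] for a in seq]
        L = len(p)
        pbar = sum(p) / L
        for d in range(1, 4):
            if kind == "moreau_broto":
                expect = sum(p[i] * p[i + d] for i in range(L - d)) / (L - d)
            elif kind == "moran":
                num = sum(
                    (p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)
                ) / (L - d)
                expect = num / (sum((x - pbar) ** 2 for x in p) / L)
            else:
                num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (
                    2 * (L - d)
                )
                expect = num / (sum((x - pbar) ** 2 for x in p) / (L - 1))
            assert v[f"{kind}.hydrophobicity.lag{d}"] == pytest.approx(
                expect, abs=TOL
            )

    def test_maxlag_too_large_raises(self):
        with pytest.raises(ValueError):
            protein.autocorrelation("MKVLW", "moran", maxlag=5)


class TestCTD:
    def test_dimension_147(self, protein_seqs):
        assert len(protein.ctd(protein_seqs[0])) == 147

    def test_homopolymer_composition_and_transitions(self):
        v = protein.ctd("A" * 20)
        for g in load_ctd_groupings():
            cls = g.class_of("A")
            assert v[f"ctd.composition.{g.attribute}.c{cls}"] == 1.0
            for pair in ("12", "13", "23"):
                assert v[f"ctd.transition.{g.attribute}.c{pair}"] == 0.0

    def test_two_residue_transition(self):
        # A and R are in different hydrophobicity classes (neutral/polar)
        v = protein.ctd("AR")
        g = next(
            g for g in load_ctd_groupings() if g.attribute == "hydrophobicity"
        )
        ca, cr = sorted((g.class_of("A"), g.class_of("R")))
        assert ca != cr
        assert v[f"ctd.transition.hydrophobicity.c{ca}{cr}"] == 1.0

    def test_composition_sums_to_one_per_attribute(self, protein_seqs):
        v = protein.ctd(protein_seqs[1])
        for g in load_ctd_groupings():
            s = sum(
                v[f"ctd.composition.{g.attribute}.c{c}"] for c in (1, 2, 3)
            )
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_distribution_in_percent_range(self, protein_seqs):
        for seq in protein_seqs:
            v = protein.ctd(seq)
            dist = [val for n, val in v if ".distribution." in n]
            assert all(0.0 <= x <= 100.0 for x in dist)

    def test_distribution_percentile_oracle(self):
        # sequence of 10 residues; count positions of class occurrences
        # directly for one attribute
        seq = "AAAARRRRAA"
        g = next(
            g for g in load_ctd_groupings() if g.attribute == "charge"
        )
        v = protein.ctd(seq)
        c_r = g.class_of("R")  # positive class, positions 5..8
        assert v[f"ctd.distribution.charge.c{c_r}.first"] == pytest.approx(50.0)
        assert v[f"ctd.distribution.charge.c{c_r}.p50"] == pytest.approx(60.0)
        assert v[f"ctd.distribution.charge.c{c_r}.p100"] == pytest.approx(80.0)


class TestConjointTriad:
    def test_dimension(self, protein_seqs):
        assert len(protein.conjoint_triad(protein_seqs[0])) == 343

    def test_single_window(self):
        v = protein.conjoint_triad("AAA")
        assert v["ct.111"] == 1.0
        assert v.values.sum() == 1.0

    def test_two_windows(self):
        v = protein.conjoint_triad("AAAA")
        assert v["ct.111"] == 2.0

    def test_window_count(self, protein_seqs):
        for seq in protein_seqs:
            v = protein.conjoint_triad(seq)
            assert v.values.sum() == len(seq) - 2


class TestSequenceOrder:
    def test_socn_default_dimension(self, protein_seqs):
        assert len(protein.socn(protein_seqs[-1])) == 60

    def test_socn_homopolymer_zero(self):
        v = protein.socn("A" * 40)
        assert np.allclose(v.values, 0.0)

    def test_socn_brute_force(self):
        seq = random_sequences("protein", 1, 10, seed=5)[0]
        matrix = default_distance_matrices()[1]  # grantham
        v = protein.socn(seq, [matrix], maxlag=2)
        for d in (1, 2):
            expect = sum(
                matrix[seq[i], seq[i + d]] ** 2 for i in range(len(seq) - d)
            )
            assert v[f"socn.{matrix.name}.d{d}"] == pytest.approx(expect, abs=TOL)

    def test_qso_default_dimension(self, protein_seqs):
        assert len(protein.qso(protein_seqs[-1])) == 100

    def test_qso_block_sums_to_one(self, protein_seqs):
        v = protein.qso(protein_seqs[-1])
        for m in default_distance_matrices():
            block = [val for n, val in v if n.startswith(f"qso.{m.name}.")]
            assert len(block) == 50
            assert sum(block) == pytest.approx(1.0, abs=1e-12)

    def test_qso_homopolymer(self):
        v = protein.qso("A" * 40)
        for m in default_distance_matrices():
            assert v[f"qso.{m.name}.A"] == pytest.approx(1.0)
            taus = [val for n, val in v if n.startswith(f"qso.{m.name}.tau")]
            assert np.allclose(taus, 0.0)


class TestPseAAC:
    def test_default_dimension_50(self, protein_seqs):
        assert len(protein.pseaac(protein_seqs[-1])) == 50

    def test_homopolymer_thetas_zero(self):
        v = protein.pseaac("A" * 40, lam=5)
        assert v["pseaac.A"] == pytest.approx(1.0)
        for j in range(1, 6):
            assert v[f"pseaac.theta{j}"] == 0.0

    def test_normalization_identity(self, protein_seqs):
        for seq in protein_seqs[-3:]:
            v = protein.pseaac(seq)
            assert (v.values >= 0).all()
            assert v.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_theta_brute_force(self):
        seq = random_sequences("protein", 1, 20, seed=9)[0]
        from biodesc.tables import default_pseaac_properties

        props = [p.standardize() for p in default_pseaac_properties()]
        lam, w = 3, 0.05
        v = protein.pseaac(seq, lam=lam, w=w)
        L = len(seq)
        thetas = []
        for j in range(1, lam + 1):
            total = 0.0
            for i in range(L - j):
                total += sum(
                    (p[seq[i]] - p[seq[i + j]]) ** 2 for p in props
                ) / len(props)
            thetas.append(total / (L - j))
        denom = L + w * sum(thetas)
        for j, th in enumerate(thetas, start=1):
            assert v[f"pseaac.theta{j}"] == pytest.approx(
                w * th / denom, abs=TOL
            )

    def test_apseaac_dimensions(self, protein_seqs):
        seq = protein_seqs[-1]
        assert len(protein.apseaac(seq)) == 50      # 20 + 2*15
        assert len(protein.apseaac(seq, lam=30)) == 80

    def test_apseaac_sums_to_one(self, protein_seqs):
        v = protein.apseaac(protein_seqs[-1])
        assert v.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestProteinAll:
    def test_total_dimension(self, protein_seqs):
        seq = protein_seqs[-1]
        v = protein.protein_all(seq)
        per_family = sum(
            len(protein.compute_family(seq, f))
            for f in protein.protein_families()
        )
        assert len(v) == per_family == 9890

    def test_names_unique_and_finite(self, protein_seqs):
        v = protein.protein_all(protein_seqs[-1])
        assert len(set(v.names)) == len(v)
        assert np.isfinite(v.values).all()

    def test_deterministic(self, protein_seqs):
        a = protein.protein_all(protein_seqs[-1])
        b = protein.protein_all(protein_seqs[-1])
        assert a == b

    def test_too_short_names_family(self):
        with pytest.raises(ValueError, match="moreau_broto"):
            protein.protein_all("MKVLW" * 4)  # L=20 < 31

    def test_dimensions_content_independent(self):
        dims = set()
        for seq in random_sequences("protein", 20, 45, seed=77):
            dims.add(len(protein.pseaac(seq)))
            dims.add(len(protein.ctd(seq)) + 1)
        assert dims == {50, 148}
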