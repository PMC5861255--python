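"""DNA descriptor families against direct-loop oracles and identities."""

import numpy as np
import pytest

from biodesc import dna
from biodesc.seqio import random_sequences
from biodesc.tables import load_oligo_properties

TOL = 1e-10


class TestKmerComposition:
    def test_single_window(self):
        v = dna.kmer_composition("AA", k=2)
        assert v["kmer2.AA"] == 1.0
        assert v.values.sum() == 1.0

    def test_basic_2mer_dimension(self, dna_seqs):
        assert len(dna.kmer_composition(dna_seqs[0], k=2)) == 16

    def test_1mer_counts(self):
        v = dna.kmer_composition("ACGT", k=1, normalize=False)
        assert all(v[f"kmer1.{b}"] == 1.0 for b in "ACGT")

    def test_count_vector_sums_to_window_count(self, dna_seqs):
        for seq in dna_seqs:
            v = dna.kmer_composition(seq, k=3, normalize=False)
            assert v.values.sum() == len(seq) - 2

    def test_normalized_sums_to_one(self, dna_seqs):
        for seq in dna_seqs:
            v = dna.kmer_composition(seq, k=2)
            assert v.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_canonical_class_counts(self):
        assert len(dna.kmer_index(2, canonical=True)) == 10
        assert len(dna.kmer_index(3, canonical=True)) == 32

    def test_canonical_revcomp_invariance(self):
        for seq in random_sequences("dna", 100, 30, seed=13):
            a = dna.kmer_composition(seq, k=2, canonical=True)
            b = dna.kmer_composition(
                dna.reverse_complement(seq), k=2, canonical=True
            )
            assert np.allclose(a.values, b.values)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dna.kmer_composition("A", k=2)


class TestCovariance:
    @pytest.mark.parametrize(
        "k,mode,dim",
        [
            (2, "auto", 76),
            (2, "cross", 2812),
            (2, "autocross", 2888),
            (3, "auto", 24),
            (3, "cross", 264),
            (3, "autocross", 288),
        ],
    )
    def test_default_dimensions(self, k, mode, dim, dna_seqs):
        assert len(dna.covariance(dna_seqs[-1], k=k, mode=mode)) == dim

    def test_homopolymer_all_zero(self):
        v = dna.covariance("A" * 12, k=2, mode="auto")
        assert np.allclose(v.values, 0.0)

    def test_auto_matches_brute_force(self):
        seq = random_sequences("dna", 1, 20, seed=21)[0]
        props = load_oligo_properties(2).subset(["santalucia_dG"])
        v = dna.covariance(seq, k=2, mode="auto", props=props, maxlag=2)
        p = props.standardize()
        series = [p.values[seq[i : i + 2]][0] for i in range(len(seq) - 1)]
        W = len(series)
        mean = sum(series) / W
        for d in (1, 2):
            expect = sum(
                (series[i] - mean) * (series[i + d] - mean)
                for i in range(W - d)
            ) / (W - d)
            assert v[f"dac.santalucia_dG.lag{d}"] == pytest.approx(
                expect, abs=TOL
            )

    def test_cross_matches_brute_force(self):
        seq = random_sequences("dna", 1, 20, seed=22)[0]
        props = load_oligo_properties(2).subset(
            ["santalucia_dG", "gc_content"]
        )
        v = dna.covariance(seq, k=2, mode="cross", props=props, maxlag=2)
        p = props.standardize()
        s1 = [p.values[seq[i : i + 2]][0] for i in range(len(seq) - 1)]
        s2 = [p.values[seq[i : i + 2]][1] for i in range(len(seq) - 1)]
        W = len(s1)
        m1, m2 = sum(s1) / W, sum(s2) / W
        for name, a, b, ma, mb in [
            ("dcc.santalucia_dG.gc_content", s1, s2, m1, m2),
            ("dcc.gc_content.santalucia_dG", s2, s1, m2, m1),
        ]:
            for d in (1, 2):
                expect = sum(
                    (a[i] - ma) * (b[i + d] - mb) for i in range(W - d)
                ) / (W - d)
                assert v[f"{name}.lag{d}"] == pytest.approx(expect, abs=TOL)

    def test_cross_with_single_property_raises(self):
        props = load_oligo_properties(2).subset(["gc_content"])
        with pytest.raises(ValueError):
            dna.covariance("ACGTACGTAC", k=2, mode="cross", props=props)

    def test_maxlag_too_large_raises(self):
        with pytest.raises(ValueError):
            dna.covariance("ACGTA", k=2, maxlag=5)


class TestPseComposition:
    def test_psednc_dimension_18(self, dna_seqs):
        v = dna.pse_composition(dna_seqs[0], k=2, lam=2)
        assert len(v) == 18

    def test_pc_psetnc_dimension_66(self, dna_seqs):
        assert len(dna.pse_composition(dna_seqs[0], k=3, lam=2)) == 66

    def test_series_dimensions(self, dna_seqs):
        # 4^k + lambda * n_properties
        assert len(
            dna.pse_composition(dna_seqs[0], k=2, correlation="series")
        ) == 16 + 2 * 38
        assert len(
            dna.pse_composition(dna_seqs[0], k=3, correlation="series")
        ) == 64 + 2 * 12

    def test_homopolymer_thetas_zero(self):
        v = dna.pse_composition("A" * 15, k=2, lam=2)
        assert v["pse2.pc.AA"] == pytest.approx(1.0)
        assert v["pse2.pc.theta1"] == 0.0
        assert v["pse2.pc.theta2"] == 0.0

    def test_sums_to_one_nonnegative(self, dna_seqs):
        for seq in dna_seqs:
            v = dna.pse_composition(seq, k=2)
            assert v.values.sum() == pytest.approx(1.0, abs=1e-12)
            assert (v.values >= 0).all()

    def test_parallel_invariant_to_property_order(self, dna_seqs):
        props = load_oligo_properties(2)
        reordered = props.subset(list(reversed(props.property_names)))
        for seq in dna_seqs[:3]:
            a = dna.pse_composition(seq, k=2, props=props)
            b = dna.pse_composition(seq, k=2, props=reordered)
            assert np.allclose(a.values, b.values)

    def test_theta_brute_force(self):
        seq = random_sequences("dna", 1, 15, seed=31)[0]
        props = load_oligo_properties(2).subset(
            ["santalucia_dG", "gc_content"]
        )
        lam, w = 2, 0.05
        v = dna.pse_composition(seq, k=2, lam=lam, w=w, props=props)
        p = props.standardize()
        prof = [list(p.values[seq[i : i + 2]]) for i in range(len(seq) - 1)]
        W = len(prof)
        thetas = []
        for j in (1, 2):
            tot = 0.0
            for i in range(W - j):
                tot += sum(
                    (prof[i][u] - prof[i + j][u]) ** 2 for u in range(2)
                ) / 2
            thetas.append(tot / (W - j))
        denom = 1.0 + w * sum(thetas)
        for j, th in enumerate(thetas, start=1):
            assert v[f"pse2.pc.theta{j}"] == pytest.approx(
                w * th / denom, abs=TOL
            )


class TestDnaAll:
    def test_total_above_6000(self, dna_seqs):
        v = dna.dna_all(dna_seqs[-1])
        assert len(v) > 6000

    def test_equals_sum_of_families(self, dna_seqs):
        seq = dna_seqs[-1]
        per_family = sum(
            len(dna.compute_family(seq, f)) for f in dna.dna_families()
        )
        assert len(dna.dna_all(seq)) == per_family

    def test_deterministic(self, dna_seqs):
        assert dna.dna_all(dna_seqs[0]) == dna.dna_all(dna_seqs[0])

    def test_names_unique(self, dna_seqs):
        v = dna.dna_all(dna_seqs[0])
        assert len(set(v.names)) == len(v)

    def test_dimensions_content_independent(self):
        dims = {
            len(dna.covariance(s, k=2, mode="auto"))
            for s in random_sequences("dna", 30, 25, seed=41)
        }
        assert dims == {76}
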