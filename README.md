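# biodesc

Numeric molecular representations for machine learning in drug discovery
and sequence bioinformatics: **biodesc** computes descriptor vectors for
small molecules (from SMILES/SDF/MOL/InChI), proteins and DNA sequences
(from FASTA or plain strings), and builds interaction features for
pairwise samples such as drug–target, protein–protein or compound–DNA
pairs.  It is aimed at practitioners who need a reproducible, uniform
featurization step in front of QSAR/QSPR models, interaction-prediction
classifiers or similarity searches.

## What it computes

**Chemicals** — 775 structural and physicochemical descriptors in twelve
groups (constitutional counts; topological indices such as the Wiener
index W = Σ_{i<j} d_ij and Balaban J; Kier–Hall connectivity χ and shape
κ indices; electrotopological-state values; Basak information indices;
Burden eigenvalues; Moreau–Broto/Moran/Geary autocorrelations; Gasteiger
charge statistics; molecular properties; MOE-type surface descriptors;
CATS pharmacophore pairs), plus 19 fingerprint families (MACCS 166,
E-state 79, Ghose–Crippen 110, FP2/FP3/FP4, PubChem 881, daylight-type,
atom pairs, torsions, ECFP/FCFP circular families, Morgan counts and
2-/3-point pharmacophore signatures).  A ten-step pretreatment pipeline
(normalization, metal disconnection, reionization, tautomer
canonicalization, neutralization, salt stripping, …) standardizes
structures before descriptor calculation.

**Proteins** — 9890 descriptors at defaults: k-mer compositions
(20/400/8000), three lagged autocorrelations of z-scored AAindex-style
property scales (8 scales × 30 lags each), composition/transition/
distribution (CTD) over seven 3-class physicochemical partitions,
conjoint-triad counts (7³ = 343), sequence-order coupling numbers
τ_d = Σ_i d(R_i, R_{i+d})² and quasi-sequence-order descriptors, and
Chou's pseudo amino acid composition

    X_r = f_r / (Σ f + w Σ θ),   X_{20+j} = w θ_j / (Σ f + w Σ θ)

in both its standard (λ = 30) and amphiphilic (λ = 15) forms.

**DNAs** — 6642 descriptors at defaults: basic and reverse-complement
k-mer compositions, dinucleotide/trinucleotide auto- and cross
covariance of physicochemical property profiles (38 and 12 scales,
lags 1–2 → 76/2812/2888 and 24/264/288 values), and parallel- and
series-correlation pseudo nucleotide compositions.

**Interactions** — five combination strategies for a pair of descriptor
vectors: same-type concatenation (both orderings, 2p), elementwise
sum+product (2p), tensor product (p²); cross-type concatenation
(p_t + p_d) and tensor product (p_t × p_d).

## Worked example

```python
>>> from biodesc import protein
>>> seq = "MKVLAAGIVQRSTWE" * 3          # a 45-residue peptide
>>> v = protein.pseaac(seq)              # pseudo amino acid composition
>>> len(v)
50
>>> round(v["pseaac.A"], 6)              # alanine component
0.124288
>>> round(v["pseaac.theta1"], 6)         # first sequence-order factor
0.002094
>>> float(v.values.sum())                # Chou normalization: sums to 1
0.9999999999999999
```

The alanine entry is its frequency (6/45) shrunk by the sequence-order
correction; the θ components carry the lag-1..30 property-correlation
signal.  On the chemistry side:

```python
>>> from biodesc.chem import parse_structure, descriptor_group, all_descriptors
>>> aspirin = parse_structure("CC(=O)Oc1ccccc1C(=O)O")
>>> descriptor_group(aspirin, "topology")["topology.W"]   # Wiener index
246.0
>>> round(descriptor_group(aspirin, "property")["property.TPSA"], 2)
63.6
>>> len(all_descriptors(aspirin))
775
```

The same computations are available from the shell:

```bash
biodesc fixtures --kind protein --n 10 --length 100 --seed 1 -o prot.fasta
biodesc protein prot.fasta -o prot.csv --families pseaac,ctd
biodesc chem molecules.smi -o chem.csv
biodesc fingerprint molecules.smi --family maccs -o fp.csv
biodesc interaction --pairs pairs.tsv --table-a prot.csv --table-b chem.csv \
    --kind cross --strategy tensor -o combined.csv
```

Invalid records are skipped with a logged reason and counted in the
summary line; identical inputs always produce byte-identical tables.

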