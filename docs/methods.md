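# Methods

This note documents the descriptor definitions, the bundled constant
tables, the parameter defaults, the numerical choices made where the
design was genuinely open, and the limitations a user should know
before trusting the output on real data.

## Sequence model and validation

Proteins are strings over the 20 canonical one-letter amino acids, DNAs
over {A,C,G,T}; positions are 1-based in all formulas.  Validators
follow a "length or zero" contract: after whitespace stripping and
case folding, a sequence containing any character outside the canonical
alphabet (ambiguity codes B/Z/X, U/O, gaps, RNA's U in DNA input)
validates to 0 rather than raising.  The zero return is the documented
failure signal; empty input likewise validates to 0.  RNA is not
transliterated — callers must pre-convert U to T.

## Protein descriptors

**k-mer composition.**  count(w) / (L − k + 1) over all 20^k words in
lexicographic order, k = 1, 2, 3.  Each vector sums to 1 exactly.

**Autocorrelation.**  Property scales are z-scored over the 20 residues
with the population SD before use ("normalized" autocorrelation); the
raw tables ship alongside in `biodesc/data/aa_properties.csv`.  With P
the per-residue property, P̄ the sequence mean and lag d = 1..30:

* Moreau–Broto: ATS(d) = Σ_{i=1}^{L−d} P_i P_{i+d} / (L − d)
* Moran: I(d) = [Σ (P_i−P̄)(P_{i+d}−P̄)/(L−d)] / [Σ (P_i−P̄)²/L]
* Geary: C(d) = [Σ (P_i−P_{i+d})²/(2(L−d))] / [Σ (P_i−P̄)²/(L−1)]

The default octet of scales is hydrophobicity (Kyte–Doolittle),
flexibility (Bhaskaran–Ponnuswamy), polarizability (Charton), free
energy of solution, accessible surface area (Chothia), residue volume
(Bigelow), steric parameter (Charton) and relative mutability
(Dayhoff) — 8 × 30 = 240 values per flavour.  On a zero-variance
(homopolymer) sequence Moran and Geary are undefined; those entries are
reported as 0.0 (degeneracy detected from a zero range of the property
series, not from the rounded variance).  User-supplied scales are
accepted as two-column text with exactly the 20 canonical rows.

**CTD.**  Seven 3-class partitions (hydrophobicity, van der Waals
volume, polarity, polarizability, charge, secondary-structure
propensity, solvent accessibility; `biodesc/data/ctd_groupings.json`).
Composition is the class fraction in [0,1]; transition
T(r,s) = (N_rs + N_sr)/(L−1) over the three unordered class pairs;
distribution reports, per class, the 1-based positions of the first and
of the ⌈q·n⌉-th occurrence (q = 25/50/75/100 %) divided by L and scaled
to a percentage, with 0 for absent classes.  Composition is a fraction
while distribution is a percentage; both conventions are deliberate and
encoded in the feature names.

**Conjoint triad.**  Residues map onto seven electrostatic/volume
classes ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C});
raw counts of the 343 class triads over the L−2 windows.

**Sequence order.**  τ_d = Σ_{i=1}^{L−d} d(R_i, R_{i+d})² for
d = 1..30 per distance matrix; the quasi-sequence-order vector places
the 20 residue frequencies and the 30 weighted coupling numbers over
the common denominator Σf + w Στ with w = 0.1, so each per-matrix block
sums to 1.  Two matrices are bundled: Grantham's chemical distance,
evaluated from his composition/polarity/volume table with the original
constants (α = 1.833, β = 0.1018, γ = 0.000399, scale 50.723), and a
**synthetic** physicochemical distance — the root-mean-square
difference of the z-scored hydrophobicity, hydrophilicity and
side-chain-mass scales — which stands in for the classic
Schneider–Wrede scale whose published values could not be sourced for
bundling.  It has the same shape, zero diagonal and role; its values
are this package's own construction and are labelled
`physchem_synthetic` in all feature names.

**PseAAC / APAAC.**  Chou's construction with w = 0.05.  Standard form:
θ_j averages Θ(R_i, R_{i+j}) = mean squared difference of the z-scored
hydrophobicity/hydrophilicity/side-chain-mass triple, λ = 30, dimension
50.  Amphiphilic form: per-lag products H_u(R_i)·H_u(R_{i+j}) kept
separate for the two hydropathy scales, λ = 15, dimension 20 + 2λ = 50.
Both vectors are nonnegative (standard form) and sum to 1.

The concatenation of all families at defaults has 9890 components.

## DNA descriptors

**k-mer composition.**  Sliding-window counts, optionally divided by
L − k + 1.  Canonical counting merges each word with its reverse
complement (class labelled by the lexicographically smaller member):
10 classes for k = 2, 32 for k = 3.  This combinatorial definition is
implemented as stated; no parameter choice yields 12 classes.

**Auto/cross covariance.**  Property profiles P_u(i) are the z-scored
per-oligonucleotide scales read along the L − k + 1 windows;
AC(u,d) and CC(u1≠u2,d) subtract the profile mean and divide by the
number of summed terms (L − k − d + 1), lags 1..2.  Cross covariance
iterates ordered property pairs, which is what makes 38 scales produce
38·37·2 = 2812 dinucleotide cross terms.  Only the forward strand is
scanned.

**Bundled oligonucleotide tables.**  38 dinucleotide and 12
trinucleotide scales (the conventional collection sizes).  Genuine
members: dinucleotide GC/purine/keto content (computed exactly),
SantaLucia unified nearest-neighbour ΔH/ΔS/ΔG°37; trinucleotide
GC/purine content and molecular weight.  The remaining scales are
seeded **synthetic** stand-ins stored in
`*_properties_synthetic.csv` with `synthetic_NN` column names: they
hold fixed uniform draws, committed once, and exist to preserve the
conventional dimensionality.  Because every scale is z-scored before
use and all identities tested are formula identities, the synthetic
columns affect no dimension and no invariant — but absolute covariance
values against those columns carry no biophysical meaning, and users
with real index collections should load them via `OligoPropertyTable`.

**Pseudo nucleotide composition.**  Parallel correlation: λ = 2 factors
θ_j averaging the mean squared property difference across all scales;
dimension 4^k + λ (18 for k = 2, 66 for k = 3).  Series correlation:
one product factor per (lag, scale) pair, dimension 4^k + λ·Λ with the
full bundled scale set (92 for k = 2, 88 for k = 3).  w = 0.05.  The
full vector sums to 1; parallel-mode output is invariant to scale
ordering.  The DNA concatenation at defaults has 6642 components.

## Chemical descriptors

Parsing, sanitization, aromaticity, SMARTS matching, Gasteiger charges,
Crippen logP/MR, TPSA and the VSA bin series are delegated to RDKit;
all remaining descriptor arithmetic is implemented here on the
heavy-atom graph.  The group manifest (775 total) is frozen in
`chem/registry.py`:

| group | dim | members |
|---|---|---|
| constitution | 30 | element/bond/ring/H-bond/rotatable counts, MW, path counts PC1–PC6 |
| topology | 35 | Wiener, mean Wiener, Balaban J, Harary, Schultz, Gutman, Zagreb M1/M2 and modified forms, quadratic, Platt, Pogliani, Ipc, BertzCT, diameter/radius/Petitjean, Xu, polarity number, hyper-Wiener, Narumi (log/ harmonic/geometric/arithmetic), information indices (TIAC, IDE, IDET, IDW, IVDE), eccentric connectivity, mean/total eccentricity, quasi-Wiener, degree distance |
| connectivity | 44 | χ path orders 0–10, mean χ1, 3/4-cluster, 4-path/cluster, 3–6 chain; valence analogues; knot differences; |χ−χv| orders 0–4 |
| estate | 237 | per-type sum/max/min of E-state indices over the 79 public atom types |
| basak | 21 | IC/SIC/CIC orders 0–6 on H-included neighborhood equivalence classes |
| burden | 64 | 8 lowest + 8 highest Burden-matrix eigenvalues × 4 weightings |
| kappa | 7 | κ1–3, κα1–3, flexibility Φ |
| autocorrelation | 3 × 32 | Moreau–Broto/Moran/Geary, lags 1–8 × 4 weightings |
| charge | 25 | Gasteiger charge statistics incl. per-element extremes, SPP, LDI |
| property | 6 | LogP, LogP², MR, TPSA, unsaturation index, hydrophilicity index |
| moe | 60 | LabuteASA, TPSA, TPSA(S,P), SlogP_VSA 12, SMR_VSA 10, PEOE_VSA 14, EState_VSA 11, VSA_EState 10 |
| cats | 150 | 5 pharmacophore point types → 15 unordered pairs × topological distance 0–9 |

Atomic weightings (autocorrelation, Burden) are carbon-relative mass,
van der Waals volume (from RDKit radii), Sanderson electronegativity
and static polarizability.  Descriptors undefined on degenerate graphs
(single atom, no bonds, zero variance) report 0.0, never NaN.  Pair
counts in CATS ignore atom pairs more than 9 bonds apart; an atom may
carry several point types and contributes a distance-0 pair per type
pair.

**Standardization.**  Ten independently toggleable steps mapped onto
RDKit's MolStandardize engines in the listed order; the full preset is
idempotent.  Step 2 (recombination of separated charges) is realized
by the same normalizer transform set as step 1 — the flag exists but
routes to one engine.  Salt stripping keeps the fragment with the most
heavy atoms; validation appends flags (multiple fragments, isotopes,
charges, exotic elements) without raising.

**Fingerprints.**  19 families with frozen lengths.  MACCS drops the
toolkit's unused bit 0 to give 166.  Ghose–Crippen uses the 110 public
Wildman–Crippen atom-type SMARTS read from the toolkit's data table at
run time.  FP2/FP3/FP4 are computed through Open Babel; FP3's public
pattern set has 55 keys, so the family's declared width of 210 carries
the pattern bits in positions 0–54 and structural zeros elsewhere.
The PubChem family implements the public 881-bit layout's element
count, ring-count and bonded-pair sections; the SMARTS-keyed sections
are fixed zero.  Pharmacophore signatures use five feature families
(donor, acceptor, positive, negative, hydrophobe); the 2-point
signature uses nine unit distance bins (15 × 9 = 135) and the 3-point
signature the frozen bins (1,2),(2,4),(4,6),(6,9) with triangle
pruning (2135).  Dimensions and determinism are contractual;
bit-for-bit parity with other toolkits is not.

## Interaction features

Same-type: concatenation returns both orderings F_ab = (F_a, F_b) and
F_ba = (F_b, F_a) (2p each); sum+product is block-concatenated (sums
then products, 2p) — the set notation admits an interleaved reading,
but blocks keep family slices contiguous; tensor product uses
k = (i−1)·p + j.  Cross-type: concatenation (p_t + p_d) and tensor
product with row-major k = (i−1)·p_d + j — the row stride must be the
second operand's length for the indexing to be bijective when
p_t ≠ p_d.  Output names are prefixed (`a.`, `b.`, `sum.`, `prod.`,
`t.*d.`) so combined vectors keep globally unique names.

## Synthetic fixtures and what tests show

`random_sequences` draws i.i.d. uniform letters with a seeded RNG; the
CLI `biodesc fixtures` exposes it.  Uniform sequences exercise every
formula and dimension but have no compositional bias, no domain
structure and no homology — passing tests therefore demonstrate
correctness of the computations, not predictive value of the features
on real proteins or genomes.  Toy molecules (ethane, n-butane, benzene,
aspirin, caffeine, …) cover rings, heteroatoms, charges and salts at
desk scale.

## Numerical choices and limitations

* Weights: QSO w = 0.1; PseAAC/APAAC and pseudo nucleotide w = 0.05.
* Float output is serialized at 6 significant digits, making repeated
  CLI runs byte-identical.
* Per-record failures in batch mode are skipped and logged, never
  silently dropped: rows written + skipped = records read.
* k-mer compositions stop at k = 3 (protein) and the covariance lags
  at 2 (DNA defaults); 3D/geometry descriptors, quantum-chemical
  charges and online database retrieval are out of scope.
* The protein-descriptor total at defaults is 9890 (= 8420 + 720 + 147
  + 343 + 160 + 100); the amphiphilic λ = 15 default is what keeps the
  APAAC block at 50.
* Member-level parity of the 775 chemical values with other toolkits is
  not claimed; the manifest makes the group totals auditable instead.
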