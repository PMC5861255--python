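"""Regenerate the versioned package data files under src/biodesc/data.

Deterministic: the synthetic oligonucleotide scales come from a fixed
seed, so rerunning this script reproduces the committed files exactly.
"""
import itertools
import json
import os

import numpy as np

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "biodesc", "data")
os.makedirs(OUT, exist_ok=True)

AA = "ACDEFGHIKLMNPQRSTVWY"

# classic published per-residue scales (keyed by one-letter code)
scales = {
    # Kyte & Doolittle hydropathy
    "hydrophobicity": dict(A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5,
                           G=-0.4, H=-3.2, I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8,
                           P=-1.6, S=-0.8, T=-0.7, W=-0.9, Y=-1.3, V=4.2),
    # Hopp & Woods hydrophilicity
    "hydrophilicity": dict(A=-0.5, R=3.0, N=0.2, D=3.0, C=-1.0, Q=0.2, E=3.0,
                           G=0.0, H=-0.5, I=-1.8, L=-1.8, K=3.0, M=-1.3, F=-2.5,
                           P=0.0, S=0.3, T=-0.4, W=-3.4, Y=-2.3, V=-1.5),
    # side-chain mass (Da)
    "side_chain_mass": dict(A=15.0, R=101.0, N=58.0, D=59.0, C=47.0, Q=72.0,
                            E=73.0, G=1.0, H=82.0, I=57.0, L=57.0, K=73.0,
                            M=75.0, F=91.0, P=42.0, S=31.0, T=45.0, W=130.0,
                            Y=107.0, V=43.0),
    # Bhaskaran & Ponnuswamy average flexibility
    "flexibility": dict(A=0.357, R=0.529, N=0.463, D=0.511, C=0.346, Q=0.493,
                        E=0.497, G=0.544, H=0.323, I=0.462, L=0.365, K=0.466,
                        M=0.295, F=0.314, P=0.509, S=0.507, T=0.444, W=0.305,
                        Y=0.420, V=0.386),
    # Charton & Charton polarizability
    "polarizability": dict(A=0.046, R=0.291, N=0.134, D=0.105, C=0.128, Q=0.180,
                           E=0.151, G=0.000, H=0.230, I=0.186, L=0.186, K=0.219,
                           M=0.221, F=0.290, P=0.131, S=0.062, T=0.108, W=0.409,
                           Y=0.298, V=0.140),
    # free energy of solution in water
    "free_energy": dict(A=-0.368, R=-1.03, N=0.0, D=2.06, C=4.53, Q=0.731,
                        E=1.77, G=-0.525, H=0.0, I=0.791, L=1.07, K=0.0,
                        M=0.656, F=1.06, P=-2.24, S=-0.524, T=0.0, W=1.60,
                        Y=4.91, V=0.401),
    # Chothia residue accessible surface area in a tripeptide (A^2)
    "asa": dict(A=115, R=225, N=160, D=150, C=135, Q=180, E=190, G=75, H=195,
                I=175, L=170, K=200, M=185, F=210, P=145, S=115, T=140, W=255,
                Y=230, V=155),
    # Bigelow residue volume (A^3)
    "volume": dict(A=52.6, R=109.1, N=75.7, D=68.4, C=68.3, Q=89.7, E=84.7,
                   G=36.3, H=91.9, I=102.0, L=102.0, K=105.1, M=97.7, F=113.9,
                   P=73.6, S=54.9, T=71.2, W=135.4, Y=116.2, V=85.1),
    # Charton steric parameter
    "steric": dict(A=0.52, R=0.68, N=0.76, D=0.76, C=0.62, Q=0.68, E=0.68,
                   G=0.00, H=0.70, I=1.02, L=0.98, K=0.68, M=0.78, F=0.70,
                   P=0.36, S=0.53, T=0.50, W=0.70, Y=0.70, V=0.76),
    # Dayhoff relative mutability
    "mutability": dict(A=100, R=65, N=134, D=106, C=20, Q=93, E=102, G=49,
                       H=66, I=96, L=40, K=56, M=94, F=41, P=56, S=120, T=97,
                       W=18, Y=41, V=74),
}

with open(os.path.join(OUT, "aa_properties.csv"), "w") as fh:
    cols = list(scales)
    fh.write("residue," + ",".join(cols) + "\n")
    for aa in AA:
        fh.write(aa + "," + ",".join(repr(float(scales[c][aa])) for c in cols) + "\n")

# Grantham's composition / polarity / volume inputs (his distance formula
# is evaluated at load time from these).
grantham = dict(
    A=(0.0, 8.1, 31), R=(0.65, 10.5, 124), N=(1.33, 11.6, 56),
    D=(1.38, 13.0, 54), C=(2.75, 5.5, 55), Q=(0.89, 10.5, 85),
    E=(0.92, 12.3, 83), G=(0.74, 9.0, 3), H=(0.58, 10.4, 96),
    I=(0.0, 5.2, 111), L=(0.0, 4.9, 111), K=(0.33, 11.3, 119),
    M=(0.0, 5.7, 105), F=(0.0, 5.2, 132), P=(0.39, 8.0, 32.5),
    S=(1.42, 9.2, 32), T=(0.71, 8.6, 61), W=(0.13, 5.4, 170),
    Y=(0.20, 6.2, 136), V=(0.0, 5.9, 84),
)
with open(os.path.join(OUT, "grantham_cpv.csv"), "w") as fh:
    fh.write("residue,composition,polarity,volume\n")
    for aa in AA:
        c, p, v = grantham[aa]
        fh.write(f"{aa},{c},{p},{v}\n")

# CTD attribute groupings: 7 physicochemical attributes x 3 classes
ctd = {
    "hydrophobicity": ["RKEDQN", "GASTPHY", "CLVIMFW"],
    "vdw_volume": ["GASCTPD", "NVEQIL", "MHKFRYW"],
    "polarity": ["LIFWCMVY", "PATGS", "HQRKNED"],
    "polarizability": ["GASDT", "CPNVEQIL", "KMHFRYW"],
    "charge": ["KR", "ANCQGHILMFPSTWYV", "DE"],
    "secondary_structure": ["EALMQKRH", "VIYCWFT", "GNPSD"],
    "solvent_accessibility": ["ALFCGIVW", "RKQEND", "MSPTHY"],
}
for name, groups in ctd.items():
    assert sorted("".join(groups)) == sorted(AA), name
with open(os.path.join(OUT, "ctd_groupings.json"), "w") as fh:
    json.dump(ctd, fh, indent=1)
    fh.write("\n")

# ---------------- DNA oligonucleotide property tables ----------------
BASES = "ACGT"
COMP = dict(zip("ACGT", "TGCA"))


def revcomp(s):
    return "".join(COMP[c] for c in reversed(s))


dinucs = ["".join(p) for p in itertools.product(BASES, repeat=2)]
trinucs = ["".join(p) for p in itertools.product(BASES, repeat=3)]

# SantaLucia (1998) unified nearest-neighbour parameters, dH (kcal/mol),
# dS (cal/mol/K), dG37 (kcal/mol); reverse complements share values.
nn = {
    "AA": (-7.9, -22.2, -1.00), "AT": (-7.2, -20.4, -0.88),
    "TA": (-7.2, -21.3, -0.58), "CA": (-8.5, -22.7, -1.45),
    "GT": (-8.4, -22.4, -1.44), "CT": (-7.8, -21.0, -1.28),
    "GA": (-8.2, -22.2, -1.30), "CG": (-10.6, -27.2, -2.17),
    "GC": (-9.8, -24.4, -2.24), "GG": (-8.0, -19.9, -1.84),
}
for d in dinucs:
    if d not in nn:
        nn[d] = nn[revcomp(d)]

with open(os.path.join(OUT, "dinucleotide_properties.csv"), "w") as fh:
    fh.write("oligo,gc_content,purine_content,keto_content,"
             "santalucia_dH,santalucia_dS,santalucia_dG\n")
    for d in dinucs:
        gc = sum(c in "GC" for c in d)
        pu = sum(c in "AG" for c in d)
        ke = sum(c in "GT" for c in d)
        h, s, g = nn[d]
        fh.write(f"{d},{gc},{pu},{ke},{h},{s},{g}\n")

# Synthetic stand-ins for the remaining conventional dinucleotide scales
# (32 of them, to reach the standard collection size of 38).  Values are
# seeded uniform draws, fixed forever in this file.
rng = np.random.default_rng(20180320)
n_syn_di = 32
with open(os.path.join(OUT, "dinucleotide_properties_synthetic.csv"), "w") as fh:
    fh.write("oligo," + ",".join(f"synthetic_{i+1:02d}" for i in range(n_syn_di)) + "\n")
    vals = np.round(rng.uniform(-2, 2, size=(16, n_syn_di)), 4)
    for d, row in zip(dinucs, vals):
        fh.write(d + "," + ",".join(map(str, row)) + "\n")

# trinucleotide genuine scales: GC content, purine content, molecular weight
# of the trideoxynucleotide (sum of dNMP residue masses).
dnmp = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}
with open(os.path.join(OUT, "trinucleotide_properties.csv"), "w") as fh:
    fh.write("oligo,gc_content,purine_content,molecular_weight\n")
    for t in trinucs:
        gc = sum(c in "GC" for c in t)
        pu = sum(c in "AG" for c in t)
        mw = round(sum(dnmp[c] for c in t), 2)
        fh.write(f"{t},{gc},{pu},{mw}\n")

n_syn_tri = 9
with open(os.path.join(OUT, "trinucleotide_properties_synthetic.csv"), "w") as fh:
    fh.write("oligo," + ",".join(f"synthetic_{i+1:02d}" for i in range(n_syn_tri)) + "\n")
    vals = np.round(rng.uniform(-2, 2, size=(64, n_syn_tri)), 4)
    for t, row in zip(trinucs, vals):
        fh.write(t + "," + ",".join(map(str, row)) + "\n")

print("wrote data files to", os.path.abspath(OUT))
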