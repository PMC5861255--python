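residue,hydrophobicity,hydrophilicity,side_chain_mass,flexibility,polarizability,free_energy,asa,volume,steric,mutability
A,1.8,-0.5,15.0,0.357,0.046,-0.368,115.0,52.6,0.52,100.0
C,2.5,-1.0,47.0,0.346,0.128,4.53,135.0,68.3,0.62,20.0
D,-3.5,3.0,59.0,0.511,0.105,2.06,150.0,68.4,0.76,106.0
E,-3.5,3.0,73.0,0.497,0.151,1.77,190.0,84.7,0.68,102.0
F,2.8,-2.5,91.0,0.314,0.29,1.06,210.0,113.9,0.7,41.0
G,-0.4,0.0,1.0,0.544,0.0,-0.525,75.0,36.3,0.0,49.0
H,-3.2,-0.5,82.0,0.323,0.23,0.0,195.0,91.9,0.7,66.0
I,4.5,-1.8,57.0,0.462,0.186,0.791,175.0,102.0,1.02,96.0
K,-3.9,3.0,73.0,0.466,0.219,0.0,200.0,105.1,0.68,56.0
L,3.8,-1.8,57.0,0.365,0.186,1.07,170.0,102.0,0.98,40.0
M,1.9,-1.3,75.0,0.295,0.221,0.656,185.0,97.7,0.78,94.0
N,-3.5,0.2,58.0,0.463,0.134,0.0,160.0,75.7,0.76,134.0
P,-1.6,0.0,42.0,0.509,0.131,-2.24,145.0,73.6,0.36,56.0
Q,-3.5,0.2,72.0,0.493,0.18,0.731,180.0,89.7,0.68,93.0
R,-4.5,3.0,101.0,0.529,0.291,-1.03,225.0,109.1,0.68,65.0
S,-0.8,0.3,31.0,0.507,0.062,-0.524,115.0,54.9,0.53,120.0
T,-0.7,-0.4,45.0,0.444,0.108,0.0,140.0,71.2,0.5,97.0
V,4.2,-1.5,43.0,0.386,0.14,0.401,155.0,85.1,0.76,74.0
W,-0.9,-3.4,130.0,0.305,0.409,1.6,255.0,135.4,0.7,18.0
Y,-1.3,-2.3,107.0,0.42,0.298,4.91,230.0,116.2,0.7,41.0
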