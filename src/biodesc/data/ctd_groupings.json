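{
 "hydrophobicity": [
  "RKEDQN",
  "GASTPHY",
  "CLVIMFW"
 ],
 "vdw_volume": [
  "GASCTPD",
  "NVEQIL",
  "MHKFRYW"
 ],
 "polarity": [
  "LIFWCMVY",
  "PATGS",
  "HQRKNED"
 ],
 "polarizability": [
  "GASDT",
  "CPNVEQIL",
  "KMHFRYW"
 ],
 "charge": [
  "KR",
  "ANCQGHILMFPSTWYV",
  "DE"
 ],
 "secondary_structure": [
  "EALMQKRH",
  "VIYCWFT",
  "GNPSD"
 ],
 "solvent_accessibility": [
  "ALFCGIVW",
  "RKQEND",
  "MSPTHY"
 ]
}
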