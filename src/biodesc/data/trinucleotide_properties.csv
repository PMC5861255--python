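oligo,gc_content,purine_content,molecular_weight
AAA,0,3,939.63
AAC,1,2,915.6
AAG,1,3,955.63
AAT,0,2,930.62
ACA,1,2,915.6
ACC,2,1,891.57
ACG,2,2,931.6
ACT,1,1,906.59
AGA,1,3,955.63
AGC,2,2,931.6
AGG,2,3,971.63
AGT,1,2,946.62
ATA,0,2,930.62
ATC,1,1,906.59
ATG,1,2,946.62
ATT,0,1,921.61
CAA,1,2,915.6
CAC,2,1,891.57
CAG,2,2,931.6
CAT,1,1,906.59
CCA,2,1,891.57
CCC,3,0,867.54
CCG,3,1,907.57
CCT,2,0,882.56
CGA,2,2,931.6
CGC,3,1,907.57
CGG,3,2,947.6
CGT,2,1,922.59
CTA,1,1,906.59
CTC,2,0,882.56
CTG,2,1,922.59
CTT,1,0,897.58
GAA,1,3,955.63
GAC,2,2,931.6
GAG,2,3,971.63
GAT,1,2,946.62
GCA,2,2,931.6
GCC,3,1,907.57
GCG,3,2,947.6
GCT,2,1,922.59
GGA,2,3,971.63
GGC,3,2,947.6
GGG,3,3,987.63
GGT,2,2,962.62
GTA,1,2,946.62
GTC,2,1,922.59
GTG,2,2,962.62
GTT,1,1,937.61
TAA,0,2,930.62
TAC,1,1,906.59
TAG,1,2,946.62
TAT,0,1,921.61
TCA,1,1,906.59
TCC,2,0,882.56
TCG,2,1,922.59
TCT,1,0,897.58
TGA,1,2,946.62
TGC,2,1,922.59
TGG,2,2,962.62
TGT,1,1,937.61
TTA,0,1,921.61
TTC,1,0,897.58
TTG,1,1,937.61
TTT,0,0,912.6
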