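name,kind,group,score,common_group
Bromodomain inhibitor,PCL,D4,96.44,
Leucine-rich repeat kinase inhibitor,PCL,D4,95.59,
HDAC inhibitor,PCL,D4,95.34,"S1, C1"
Topoisomerase inhibitor,PCL,D4,91.09,
PI3K inhibitor,PCL,D4,89.36,
MEK inhibitor,PCL,D4,88.85,
SRC inhibitor,PCL,D4,87.13,
Minor histocompatibility,PCL,D4,85.11,
HSP inhibitor,PCL,D4,83.51,C1
General transcription factors group 2 LOF,PCL,D4,80.25,
MTOR inhibitor,PCL,A1,90.22,
Vesicular transport LOF,PCL,S1,98.00,C1
Proteasome inhibitor,PCL,S1,97.37,C1
Heat shock 70 kDa proteins LOF,PCL,S1,96.55,
HIF activator,PCL,S1,93.31,C1
HIV protease inhibitor,PCL,S1,91.09,C1
HDAC inhibitor,PCL,S1,86.58,"D4; C1"
Protein phosphatase catalytic subunits LOF,PCL,S1,86.34,
Wnt family GOF,PCL,S1,84.05,C1
EIF Proteins LOF,PCL,S1,81.50,C1
Wnt family GOF,PCL,C1,96.79,S1
BCL inhibitor,PCL,C1,96.24,
HDAC inhibitor,PCL,C1,95.11,"D4; S1"
HIV protease inhibitor,PCL,C1,94.78,S1
PKC activator,PCL,C1,93.67,
PKC inhibitor,PCL,C1,93.28,
Vesicular transport LOF,PCL,C1,93.12,S1
HSP inhibitor,PCL,C1,87.43,D4
EIF Proteins LOF,PCL,C1,87.11,S1
IKK inhibitor,PCL,C1,85.91,
X linked mental retardation group 2 LOF,PCL,C1,85.79,
HIF activator,PCL,C1,85.12,S1
Proteasome inhibitor,PCL,C1,82.82,S1
EGFR inhibitor,PCL,C1,80.10,
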