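# Synthetic placeholder consensus library for avian control-region boxes.
# The primary literature does not print the consensus sequences of these
# elements (they are recognized by similarity to other vertebrates), so the
# sequences below are fixed arbitrary stand-ins used by the simulator and
# the test-suite; replace this file with a curated library for real data.
# Columns: name, IUPAC consensus, domain (ETAS|Central|CSB), max_mismatch_fraction
poly-C	CCCCCCCC	ETAS	0.10
ETAS	TACATGTAATYATGTACCAGCTTAT	ETAS	0.20
CSB1-like	ATGGCCCATTYACGTTAAGG	ETAS	0.20
F-box	GTTCGATAATCRACGATTCAAG	Central	0.20
E-box	AGGGAACCTYTAGGACTCAC	Central	0.20
D-box	CCTGGTTCCTRGATCAGGCA	Central	0.20
C-box	TGAACTATYGGCATCTGGTT	Central	0.20
CSBa	CAAGTGCTWGTACCGAACTG	Central	0.20
CSBb	AACGTGGCRATTAGCCTGAC	Central	0.20
Bird-box	TTATGGTYACGGAGCATTAA	Central	0.20
CSB1	TTAATGCTYGATAGACATAACCG	CSB	0.20
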