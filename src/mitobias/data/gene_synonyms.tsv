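# alias (upper-cased, spaces stripped) -> canonical symbol
# Edit freely: unknown annotation labels pass through unchanged.
COX1	COI
COXI	COI
CO1	COI
COI	COI
COX2	COII
COXII	COII
CO2	COII
COII	COII
COX3	COIII
COXIII	COIII
CO3	COIII
COIII	COIII
CYTB	Cytb
COB	Cytb
CYB	Cytb
MT-CYB	Cytb
ATP6	ATP6
ATPASE6	ATP6
ATP8	ATP8
ATPASE8	ATP8
NAD1	ND1
NADH1	ND1
ND1	ND1
NAD2	ND2
NADH2	ND2
ND2	ND2
NAD3	ND3
NADH3	ND3
ND3	ND3
NAD4	ND4
NADH4	ND4
ND4	ND4
NAD4L	ND4L
NADH4L	ND4L
ND4L	ND4L
NAD5	ND5
NADH5	ND5
ND5	ND5
NAD6	ND6
NADH6	ND6
ND6	ND6
12SRRNA	12S rRNA
12SRIBOSOMALRNA	12S rRNA
RRNS	12S rRNA
S-RRNA	12S rRNA
16SRRNA	16S rRNA
16SRIBOSOMALRNA	16S rRNA
RRNL	16S rRNA
L-RRNA	16S rRNA
D-LOOP	control_region
DLOOP	control_region
CONTROLREGION	control_region
CONTROL_REGION	control_region
TRNF	tRNA-Phe
TRNA-PHE	tRNA-Phe
TRNV	tRNA-Val
TRNA-VAL	tRNA-Val
TRNL	tRNA-Leu
TRNL2	tRNA-Leu(UUR)
TRNA-LEU(UUR)	tRNA-Leu(UUR)
TRNL1	tRNA-Leu(CUN)
TRNA-LEU(CUN)	tRNA-Leu(CUN)
TRNI	tRNA-Ile
TRNA-ILE	tRNA-Ile
TRNQ	tRNA-Gln
TRNA-GLN	tRNA-Gln
TRNM	tRNA-Met
TRNA-MET	tRNA-Met
TRNW	tRNA-Trp
TRNA-TRP	tRNA-Trp
TRNA-ALA	tRNA-Ala
TRNN	tRNA-Asn
TRNA-ASN	tRNA-Asn
TRNC	tRNA-Cys
TRNA-CYS	tRNA-Cys
TRNY	tRNA-Tyr
TRNA-TYR	tRNA-Tyr
TRNS	tRNA-Ser
TRNS1	tRNA-Ser(UCN)
TRNA-SER(UCN)	tRNA-Ser(UCN)
TRNS2	tRNA-Ser(AGY)
TRNA-SER(AGY)	tRNA-Ser(AGY)
TRND	tRNA-Asp
TRNA-ASP	tRNA-Asp
TRNK	tRNA-Lys
TRNA-LYS	tRNA-Lys
TRNG	tRNA-Gly
TRNA-GLY	tRNA-Gly
TRNR	tRNA-Arg
TRNA-ARG	tRNA-Arg
TRNH	tRNA-His
TRNA-HIS	tRNA-His
TRNT	tRNA-Thr
TRNA-THR	tRNA-Thr
TRNP	tRNA-Pro
TRNA-PRO	tRNA-Pro
TRNE	tRNA-Glu
TRNA-GLU	tRNA-Glu
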