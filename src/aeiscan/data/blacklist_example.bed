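# Example region blacklist (hg19), 0-based half-open BED3+label.
# APPROXIMATE intervals around regions frequently reported as
# mapping-conflictive in retinal RNA-seq: the OPN1LW/OPN1MW opsin gene
# array and several 3'UTRs. Coordinates are rough gene-scale bounds for
# documentation and testing only — derive exact intervals from your own
# alignments before production use.
chrX	153400000	153460000	OPN1LW_MW_array_approx
chr12	1900000	1920000	CACNA2D4_3pUTR_approx
chr19	48325000	48347000	CRX_3pUTR_approx
chr1	19540000	19580000	EMC1_3pUTR_approx
chr5	149237000	149325000	PDE6A_3pUTR_approx
chr8	10460000	10480000	RP1L1_3pUTR_approx
chr11	8040000	8130000	TUB_3pUTR_approx
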