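"""Published *petB* primer sets for marine *Synechococcus* metabarcoding.

Two protocols target the 657-bp *petB* gene (cytochrome b6):

* the standard single-round PCR with petB-F / petB-R (597-bp amplicon), and
* the nested protocol combining petB-F with the degenerate petB-634R in
  round 1 (613 bp) and the degenerate petB-50F with petB-R in round 2
  (569 bp).

Gene positions are 1-based inclusive on the gene-forward strand of the
*Synechococcus* sp. WH8109 reference; amplicon lengths include the primers.
The degenerate primers are given here at their full synthesized lengths
(17-mer petB-50F, 20-mer petB-634R).
"""

from nestprime.seqcore import DegenerateOligo

#: Total length of the petB gene in the WH8109 reference (bp).
PETB_GENE_LENGTH = 657

PETB_F = DegenerateOligo(
    name="petB-F",
    sequence="TACGACTGGTTCCAGGAACG",
    direction="forward",
    gene_start=22,
    gene_end=41,
)

PETB_R = DegenerateOligo(
    name="petB-R",
    sequence="GAAGTGCATGAGCATGAA",
    direction="reverse",
    gene_start=601,
    gene_end=618,
)

PETB_50F = DegenerateOligo(
    name="petB-50F",
    sequence="TYCAGGACATYGCTGAY",
    direction="forward",
    gene_start=50,
    gene_end=66,
)

PETB_634R = DegenerateOligo(
    name="petB-634R",
    sequence="GCTTVCGRATCATCARGAAG",
    direction="reverse",
    gene_start=615,
    gene_end=634,
)
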