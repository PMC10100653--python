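# nestprime

Degenerate primer design, in-silico nested PCR and amplicon
taxonomic-resolution statistics for marker-gene metabarcoding.

`nestprime` is built for the situation faced when surveying marine
*Synechococcus* diversity with the single-copy *petB* gene (cytochrome b6):
template DNA can be too dilute for a standard PCR (e.g. flow
cytometry-sorted cells), so a **nested** protocol is needed — two sequential
amplifications in which the second round's primers bind inside the first
round's product.  Designing such primer sets over a taxonomy-annotated
reference alignment, predicting what they amplify, and checking that the
shorter amplicon still resolves the taxonomy are the three jobs this
toolkit does.  Everything is generic over any single-copy marker; the
published *petB* primer sets ship as constants in `nestprime.petb`.

## What it computes

**Primer math.** A degenerate primer is an IUPAC string; its *degeneracy*
is the number of plain sequences it represents, `∏ᵢ |S(cᵢ)|` over the
per-position IUPAC base sets `S`.  GC% is ambiguity-weighted
(`Y → 0.5`, `V → 2/3`), Tm is the Wallace rule `2(A+T) + 4(G+C)` (mean and
range over expansions), and hairpin/self-dimer screens use IUPAC-aware
antiparallel complementarity.

**Design criteria.** Candidate primers are minimal degenerate consensi over
conserved alignment windows, accepted only if: ≤ 3 mismatches against every
target record (mismatch = disjoint IUPAC base sets, i.e. the min Hamming
distance over expansions); no terminal ambiguity; degeneracy ≤ cap; length
15–20 nt; forward/reverse Tm gap ≤ 4 °C; no indels in the window; no
hairpins or self-dimers.  An amplicon-length target (< 550 bp for 2×300 bp
chemistry) is advisory.

**In-silico PCR.** Binding sites are found on both strands under a mismatch
tolerance (3′-terminal mismatches kill a site by default); an amplicon runs
from the forward footprint's 5′ end to the reverse footprint's 3′ end,
primers included.  Nested amplification re-amplifies round-1 *products
only* and maps round-2 coordinates back to the template.

**Resolution & validation.** A reference database truncated to the amplicon
region is scored by within-/between-group pairwise identity; a group pair
is *resolvable* iff max between-group identity < min within-group identity
of both groups.  ASV assignments are validated by translating each ASV
(bacterial code, frame with fewest stops) and requiring ≥ 95% best protein
identity to the translated references of its assigned group.  Non-
overlapping read pairs are joined with a 10-N spacer.

## Worked example

```bash
python examples/02_insilico_nested_pcr.py
```

```
template: petB_benchmark_template, 657 bp
standard PCR  : 597 bp (22-618), insert 559 bp (42-600)
nested round 1: 613 bp (22-634)
nested round 2: 569 bp (50-618), insert 534 bp
```

The benchmark template is a seeded 657-bp *petB*-like gene carrying perfect
binding sites for the published primers at their gene coordinates
(1-based, inclusive).  The standard pair petB-F (22–41) × petB-R (601–618)
yields the 597-bp product; the nested protocol amplifies 613 bp with
petB-F × petB-634R (615–634) in round 1 and then 569 bp with petB-50F
(50–66) × petB-R from that product in round 2.  Inserts are the amplicons
minus both primer footprints — the part that is actually sequenced.

```bash
python examples/01_primer_metrics.py
```

```
primer     sequence                deg    GC%  Tm mean     Tm range
petB-F     TACGACTGGTTCCAGGAACG      1   55.0     62.0        62-62
petB-R     GAAGTGCATGAGCATGAA        1   44.4     52.0        52-52
petB-50F   TYCAGGACATYGCTGAY         8   50.0     51.0        48-54
petB-634R  GCTTVCGRATCATCARGAAG     12   48.3     59.3        56-62
```

petB-50F's degeneracy 8 comes from its three Y positions (2³); petB-634R's
12 from V×R×R (3×2×2).  The remaining examples cover design scanning over a
synthetic alignment (`03`), amplicon-region resolvability (`04`) and ASV
validation statistics (`05`).

A `nestprime` command-line tool wraps the same operations (`oligo report`,
`primer profile|sites`, `design scan`, `ispcr`, `resolve`, `validate`,
`simulate refdb|template|asvs`); every report is TSV with a provenance
header, byte-identical for identical configuration and seed.

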