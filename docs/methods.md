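# Methods

This note records the models, conventions and numerical choices behind
`nestprime`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Coordinates and orientation

All coordinates are 1-based and inclusive on the gene-forward strand.  A
reverse primer is stored 5′→3′ as synthesized — the reverse-complement of
its forward-strand footprint — while its `gene_start`/`gene_end` refer to
that footprint.  Amplicon length therefore equals
`reverse.gene_end − forward.gene_start + 1`, primers included; the insert
is the region strictly between the footprints.  `U` is normalized to `T`,
lowercase to uppercase; the alignment gap `-` is legal only inside a
database flagged as aligned, never inside a primer.

## Mismatch model

A primer position mismatches a template position iff their IUPAC base sets
are disjoint (`N` is compatible with everything).  This is symmetric and
equals the minimum Hamming distance over all pairs of plain expansions — a
generous rule chosen because reference databases themselves contain
ambiguity codes, and an intersection rule never rejects a duplex that some
synthesized variant could form.  The same rule scores nucleotide identity
in the resolution module, for consistency.

In-silico PCR requires a compatible 3′-terminal base by default
(`require_3prime_match=True`): a 3′ mismatch generally prevents polymerase
extension.  Binding-site searches for profiling default to unanchored with
the anchor as an opt-in, since exclusion claims about off-target taxa are
usually stated without an anchoring rule.

## Oligo metrics

* **Degeneracy** is the product of per-position base-set sizes; internally
  a plain oligo has degeneracy 1.  Report layers that mimic the common
  table convention can map 1 → 0 (`--table-style-deg`).
* **GC%** uses set-fraction weighting: a code contributes
  `|S ∩ {G,C}| / |S|`.  This equals the mean plain GC% over expansions.
* **Tm** offers the Wallace rule `2(A+T)+4(G+C)` (default) and the basic-GC
  rule `64.9 + 41(GC − 16.4)/N`.  Both are linear in the GC count, so the
  mean over expansions is computed analytically, with min/max from the
  per-position extremes.  These are screening estimates only; annealing
  temperatures used in actual protocols are cycling parameters, not Tm
  predictions, and nearest-neighbor thermodynamics is out of scope.
* **Hairpin screen** (default stem ≥ 4, loop 3–12): every maximal pair of
  in-oligo segments that are antiparallel-complementary, where degenerate
  positions count as complementary if *any* expansion pair is
  Watson–Crick — a conservative screen.
* **Self-dimer screen** (defaults: run ≥ 8 anywhere, or ≥ 4 touching the
  3′-terminal 5 bases of either copy): maximal complementary runs over all
  antiparallel registers of the oligo against itself.  The thresholds are
  common practice for primer QC; no published standard exists.

## Design scanner

Candidates are built per alignment window (every start, every length in
[15, 20] by default) as the **minimal set-cover consensus**: each column's
code is the smallest IUPAC set containing every observed base.  An optional
minor-allele threshold (default 0 = strict) ignores bases seen in at most
that fraction of sequences, a deliberate deviation knob for real databases
containing sequencing errors.  The criterion audit stores per-criterion
(pass, reason) and is idempotent.  A window containing a gap in any target
record fails the indel criterion outright.  Candidates are ranked by
(coverage desc, degeneracy asc, window start asc); the ranking is a toolkit
decision — coverage is the design goal, low degeneracy the tie-breaker
that favours specific mixes.  The Tm-gap criterion is evaluated at pairing,
using the Wallace mean over expansions.  The amplicon-length target
(550 bp) is advisory: pairs exceeding it carry a flag rather than being
rejected, because a design may legitimately accept a longer product when
no shorter conserved region exists.

Nested classification: an inner pair is valid against an outer pair when
both inner footprints lie inside the outer amplicon and each inner primer
is either identical to the same-direction outer primer (shared) or
internal by at least `min_offset` (default 5 bp — a toolkit default; the
motivating concern is only that near-identical annealing regions add no
specificity).  Both-shared is invalid; one-shared is semi-nested; none
shared is fully nested.

## In-silico PCR

All (forward site, downstream reverse site) combinations within
`max_product` (default 5000 bp, bounding combinatorial pairings) become
products.  Nested amplification is a strict containment contract: round 2
runs **only** on round-1 product strings, so an inner pair that binds the
template outside the outer product yields nothing.  Round-2 coordinates
are mapped back through the parent product.  Circular templates are not
supported (gene-scale loci).  Polymerase errors and chimera formation —
a real artifact of nested protocols — are not simulated.

## Resolution and validation

Pairwise identity is either ungapped (equal lengths, IUPAC-compatible
positions count as matches) or global-alignment (match 1, mismatch −1,
gap −2; identity over all alignment columns, gaps included).
**Resolvability** of a group pair is strict identity separation:
`max(between) < min(within)` for both groups; violating sequence pairs are
listed.  This is a distance-based stand-in with the same decision
semantics as inspecting a phylogeny of the truncated region — it asks
whether the shorter amplicon still separates the groups — chosen because
maximum-likelihood tree inference is outside this package's scope.

ASV validation translates with the bacterial/plastid code (table 11); a
degenerate codon yields the unique amino acid if all expansions agree,
else `X` (conservative, since ASVs may contain any base).  The reading
frame is the one with the fewest stop codons, ties to the lower frame.
Each ASV's **best** global-alignment protein identity against the
translated references of its assigned group is compared to the threshold
(default 95%); best-hit rather than mean is used because the question is
whether *any* reference supports the assignment, and the check is against
the assigned group (not the whole database, available behind a flag)
because it validates a classifier's output rather than re-classifying.
Untranslatable ASVs (< 1 codon) are excluded from the rate denominator and
counted separately.

Read concatenation joins a forward read, `spacer_n` N bases (default 10)
and the reverse-complement of the reverse read — the standard maneuver
when the amplicon exceeds the combined read length so genuine merging is
impossible.

## Synthetic data

`make_reference_db` draws a uniform root sequence, derives clade ancestors,
subclade ancestors and records by independent per-site substitutions
(uniform over the three alternative bases — a Jukes–Cantor-style model,
the simplest defensible choice for fixtures), and restores planted
conserved windows verbatim.  The single column flanking each planted
window is forced to differ between clades so the planted window is the
*unique* fully conserved region of its length — the scanner ground truth
is unambiguous by construction.  Defaults (3 clades × 2 subclades × 4
records, 657-bp gene, divergences 15% / 6% / 2%) mirror the scale of
hierarchy found in curated picocyanobacterial marker databases while
staying small enough for exhaustive scans.  No indels are simulated: the
target marker is length-conserved and the design criteria reject gapped
windows anyway (`inject_gap` exists solely to exercise that rejection).

Expected pairwise identity under this model, used by the parameter-recovery
tests: two branches of rate *p* from one ancestor differ per site with
probability `q = 2p(1−p) + (2/3)p²`.

`make_benchmark_template` builds a 657-bp gene carrying one concrete
expansion of each published primer footprint at its published coordinate
(the overlapping reverse footprints at 615–618 agree because both primers
end in the same fixed bases there), seeded filler elsewhere, and verifies
internally that each primer has exactly one zero-mismatch site.

`simulate_asvs` draws ASVs from group amplicons with substitution noise,
plus a configurable spurious fraction (random sequence, genuine label)
whose identity it records — so validation statistics can be checked
against generator bookkeeping exactly.

**What passing tests show — and don't.**  The generators contain no indels,
no chimeras, no read-quality structure and no compositional bias, and
their divergence is homogeneous along the gene.  Tests passing on them
demonstrate the *operations* are correct (coordinates, contracts,
statistics, recovery of known parameters), not that any particular primer
set performs well on real environmental data.

## Problem sizes

The default test and benchmark runs use small instances chosen to exercise
every code path exhaustively: reference databases of 12–24 records of
200–657 bp, 10–20 generator seeds per property, 10⁴ random IUPAC pairs for
the mismatch oracle, and oligos ≤ 30 nt for the quadratic structure-screen
oracles.  All scale linearly (or quadratically in oligo length) if
enlarged.

## Known limitations

* No thermodynamic duplex model (ΔG, salt correction); Tm rules are
  counting heuristics.
* No multiple-sequence alignment or tree inference; aligned input is a
  prerequisite, and resolvability is distance-based.
* Cross-dimer screening across whole primer panels is limited to the
  pairwise checks done at pairing time.
* Chimera formation, the characteristic nested-PCR artifact, is observed
  in real data but not modelled here.
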