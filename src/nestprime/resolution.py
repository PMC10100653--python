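"""Amplicon-region taxonomic resolution and ASV validation statistics.

Given a reference database truncated to the amplified region, this module
asks whether the shorter amplicon still separates taxonomic groups
(within- versus between-group pairwise identity), and validates amplicon
sequence variants (ASVs) by translating them and requiring a minimum
protein identity to the translated references of their assigned group.
It also implements the read-concatenation maneuver used when paired-end
reads do not overlap: joining them with a spacer of N bases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import Align

from nestprime.design import PrimerPair
from nestprime.ispcr import amplify, trim_primers
from nestprime.seqcore import (
    IUPAC_SETS,
    ReferenceDB,
    ReferenceRecord,
    normalize_sequence,
    reverse_complement,
    translate,
)


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def pairwise_identity(a: str, b: str, mode: str = "ungapped") -> float:
    """Percent identity between two nucleotide sequences.

    mode='ungapped' requires equal lengths and scores IUPAC-compatible
    (intersecting) codes as matches; mode='global_align' aligns globally
    (match 1, mismatch -1, gap -2) and reports identities over all
    alignment columns, gap columns included.
    """
    a = normalize_sequence(a)
    b = normalize_sequence(b)
    if mode == "ungapped":
        if len(a) != len(b):
            raise ValueError(
                f"ungapped identity needs equal lengths ({len(a)} vs {len(b)}); "
                "use mode='global_align'"
            )
        matches = sum(1 for x, y in zip(a, b) if not IUPAC_SETS[x].isdisjoint(IUPAC_SETS[y]))
        return 100.0 * matches / len(a)
    if mode == "global_align":
        return _alignment_identity(a, b, _nt_aligner(), _nt_match)
    raise ValueError(f"unknown mode {mode!r}")


def _nt_match(x: str, y: str) -> bool:
    return not IUPAC_SETS.get(x, frozenset(x)).isdisjoint(IUPAC_SETS.get(y, frozenset(y)))


def _alignment_identity(a: str, b: str, aligner: Align.PairwiseAligner,
                        match_fn) -> float:
    aln = aligner.align(a, b)[0]
    cols = 0
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            matches += match_fn(a[i], b[j])
    # total columns = aligned columns + gap columns
    aligned_cols = sum(e - s for s, e in aln.aligned[0])
    gap_cols = (len(a) - aligned_cols) + (len(b) - aligned_cols)
    cols = aligned_cols + gap_cols
    return 100.0 * matches / cols


def protein_identity(a: str, b: str) -> float:
    """Global-alignment identity between two protein sequences (percent)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return _alignment_identity(a, b, aligner, lambda x, y: x == y and x != "X")


def truncate_db_to_amplicon(
    db: ReferenceDB,
    pair: PrimerPair,
    include_primers: bool = True,
    max_mismatches: int = 3,
    require_3prime_match: bool = False,
) -> tuple[ReferenceDB, list[str]]:
    """Replace each record by its in-silico amplicon for a primer pair.

    Returns the truncated database (taxonomy preserved) and the drop-list
    of record ids where the pair produced no product.  With
    ``include_primers=False`` each record is trimmed to the insert.
    """
    kept = []
    dropped = []
    for rec in db.records:
        products = amplify(rec, pair.forward, pair.reverse,
                           max_mismatches, require_3prime_match)
        if not products:
            dropped.append(rec.id)
            continue
        # "the" amplicon: fewest total primer mismatches, then leftmost/shortest
        amp = min(products, key=lambda a: (a.fwd_site.mismatches
                                           + a.rev_site.mismatches,
                                           a.start, a.length))
        seq = amp.sequence if include_primers else trim_primers(amp)[0]
        kept.append(ReferenceRecord(rec.id, seq, rec.taxonomy))
    return ReferenceDB(kept, aligned=False), dropped


@dataclass(frozen=True)
class SimilarityReport:
    """Within-group pairwise-identity summary, optionally vs other groups."""

    group: str
    n_sequences: int
    within_min: float | None
    within_mean: float | None
    between_max: dict[str, float] | None = None
    singleton: bool = False


def group_similarity(
    records: ReferenceDB | list[ReferenceRecord],
    group_level: str = "clade",
    mode: str = "ungapped",
    between: bool = False,
) -> list[SimilarityReport]:
    """Within-group (and optionally between-group) pairwise identity.

    Groups with a single sequence are flagged as singletons, not scored.
    With ``between=True`` each report carries, for every other group, the
    maximum identity between any cross-group sequence pair.
    """
    db = records if isinstance(records, ReferenceDB) else ReferenceDB(list(records))
    groups = db.groups(group_level)
    reports = []
    for name in sorted(groups):
        seqs = [r.sequence for r in groups[name]]
        if len(seqs) < 2:
            reports.append(SimilarityReport(name, len(seqs), None, None,
                                            singleton=True))
            continue
        idents = [
            pairwise_identity(x, y, mode)
            for x, y in itertools.combinations(seqs, 2)
        ]
        between_max = None
        if between:
            between_max = {}
            for other in sorted(groups):
                if other == name:
                    continue
                cross = [
                    pairwise_identity(x.sequence, y.sequence, mode)
                    for x in groups[name]
                    for y in groups[other]
                ]
                between_max[other] = max(cross)
        reports.append(
            SimilarityReport(
                group=name,
                n_sequences=len(seqs),
                within_min=min(idents),
                within_mean=sum(idents) / len(idents),
                between_max=between_max,
            )
        )
    return reports


@dataclass(frozen=True)
class ResolvabilityVerdict:
    group_a: str
    group_b: str
    resolvable: bool
    between_max: float
    within_min_a: float
    within_min_b: float
    entangled_pairs: list[tuple[str, str, float]]


def resolvability(
    records: ReferenceDB | list[ReferenceRecord],
    group_level: str = "subclade",
    mode: str = "ungapped",
) -> list[ResolvabilityVerdict]:
    """Can the amplicon region distinguish each pair of groups?

    A pair is resolvable iff the maximum between-group identity is strictly
    below the minimum within-group identity of BOTH groups; otherwise it is
    entangled and the violating sequence pairs are listed.  Groups with a
    single sequence use within-min 100 (a singleton is trivially coherent).
    """
    db = records if isinstance(records, ReferenceDB) else ReferenceDB(list(records))
    groups = db.groups(group_level)
    names = sorted(g for g in groups)
    within_min: dict[str, float] = {}
    for name in names:
        seqs = [r.sequence for r in groups[name]]
        if len(seqs) < 2:
            within_min[name] = 100.0
        else:
            within_min[name] = min(
                pairwise_identity(x, y, mode)
                for x, y in itertools.combinations(seqs, 2)
            )
    verdicts = []
    for a, b in itertools.combinations(names, 2):
        threshold = min(within_min[a], within_min[b])
        between_max = 0.0
        entangled = []
        for ra in groups[a]:
            for rb in groups[b]:
                ident = pairwise_identity(ra.sequence, rb.sequence, mode)
                between_max = max(between_max, ident)
                if ident >= threshold:
                    entangled.append((ra.id, rb.id, ident))
        verdicts.append(
            ResolvabilityVerdict(
                group_a=a,
                group_b=b,
                resolvable=not entangled,
                between_max=between_max,
                within_min_a=within_min[a],
                within_min_b=within_min[b],
                entangled_pairs=entangled,
            )
        )
    return verdicts


def choose_frame(nt: str) -> int:
    """Reading frame with the fewest stop codons; ties go to the lower frame."""
    best_frame, best_stops = 1, None
    for frame in (1, 2, 3):
        if len(nt) - (frame - 1) < 3:
            continue
        stops = translate(nt, frame).count("*")
        if best_stops is None or stops < best_stops:
            best_frame, best_stops = frame, stops
    if best_stops is None:
        raise ValueError("sequence shorter than one codon in every frame")
    return best_frame


@dataclass(frozen=True)
class AssignmentCheck:
    asv_id: str
    assigned_group: str
    best_identity: float | None
    correctly_assigned: bool
    excluded: bool = False  # untranslatable, not counted in the rate


@dataclass(frozen=True)
class AssignmentSummary:
    checks: list[AssignmentCheck]
    rate_overall: float | None
    rate_per_group: dict[str, float]
    n_excluded: int


def protein_assignment_check(
    asvs: list[tuple[str, str, str]],
    db: ReferenceDB | list[ReferenceRecord],
    group_level: str = "clade",
    threshold: float = 95.0,
    frame: int | None = None,
    whole_db: bool = False,
) -> AssignmentSummary:
    """Validate ASV taxonomic assignments at the protein level.

    ``asvs`` is a list of (asv_id, sequence, assigned_group) triples.  Each
    ASV is translated (frame chosen by fewest stop codons unless ``frame``
    is given) and compared by global-alignment protein identity against the
    translated references of its assigned group (or the whole database with
    ``whole_db=True``); an ASV is correctly assigned iff its best identity
    reaches ``threshold``.  ASVs shorter than one codon are excluded from
    the rate denominator and reported.
    """
    ref_db = db if isinstance(db, ReferenceDB) else ReferenceDB(list(db))
    groups = ref_db.groups(group_level)
    prot_cache: dict[str, list[str]] = {}

    def group_proteins(name: str) -> list[str]:
        if name not in prot_cache:
            recs = ref_db.records if whole_db else groups.get(name, [])
            prots = []
            for r in recs:
                seq = r.ungapped
                if len(seq) >= 3:
                    prots.append(translate(seq, choose_frame(seq)))
            prot_cache[name] = prots
        return prot_cache[name]

    checks = []
    for asv_id, seq, assigned in asvs:
        try:
            seq = normalize_sequence(seq)
        except ValueError:
            checks.append(AssignmentCheck(asv_id, assigned, None, False, excluded=True))
            continue
        if len(seq) < 3:
            checks.append(AssignmentCheck(asv_id, assigned, None, False, excluded=True))
            continue
        prot = translate(seq, frame if frame is not None else choose_frame(seq))
        refs = group_proteins(assigned)
        if not refs:
            checks.append(AssignmentCheck(asv_id, assigned, None, False))
            continue
        best = max(protein_identity(prot, rp) for rp in refs)
        checks.append(AssignmentCheck(asv_id, assigned, best, best >= threshold))

    scored = [c for c in checks if not c.excluded]
    rate = 100.0 * sum(c.correctly_assigned for c in scored) / len(scored) if scored else None
    per_group: dict[str, float] = {}
    for g in sorted({c.assigned_group for c in scored}):
        gs = [c for c in scored if c.assigned_group == g]
        per_group[g] = 100.0 * sum(c.correctly_assigned for c in gs) / len(gs)
    return AssignmentSummary(
        checks=checks,
        rate_overall=rate,
        rate_per_group=per_group,
        n_excluded=sum(c.excluded for c in checks),
    )


def concat_read_pair(fwd_read: str, rev_read: str, spacer_n: int = 10) -> str:
    """Join non-overlapping paired-end reads with a spacer of N bases.

    Returns ``fwd_read + 'N' * spacer_n + reverse_complement(rev_read)``;
    the reverse read is given in its sequenced orientation.  Used when the
    amplicon is longer than the combined read lengths so true merging is
    impossible; the N spacer keeps downstream k-mer classifiers usable.
    """
    if spacer_n < 0:
        raise ValueError("spacer_n must be >= 0")
    fwd = normalize_sequence(fwd_read)
    rev = normalize_sequence(rev_read)
    return fwd + "N" * spacer_n + reverse_complement(rev)
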