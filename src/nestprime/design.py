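"""Criterion-based degenerate primer discovery and pair/nested-set assembly.

A candidate primer is the minimal degenerate consensus over a conserved
window of an aligned reference database, accepted only if it satisfies the
full design criterion set:

(i)    at most ``max_mismatches`` mismatches against every target record;
(ii)   no ambiguity in the terminal bases at either end;
(iii)  degeneracy at most ``max_degeneracy``;
(iv)   length within [length_min, length_max];
(v)    forward/reverse Tm gap at most ``max_tm_gap`` (checked at pairing);
(vi)   no insertions or deletions (alignment gaps) among the target
       records inside the window;
(vii)  no hairpins or self-dimerization.

Amplicon lengths include both primers: length = reverse.gene_end -
forward.gene_start + 1 in 1-based inclusive gene coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from nestprime.oligo_metrics import (
    degeneracy,
    end_check,
    hairpin_screen,
    self_dimer_screen,
    tm_estimate,
)
from nestprime.seqcore import (
    IUPAC_SETS,
    SET_TO_CODE,
    DegenerateOligo,
    ReferenceDB,
    reverse_complement,
)
from nestprime.binding import count_mismatches


@dataclass(frozen=True)
class DesignCriteria:
    """Thresholds for candidate acceptance.

    ``target_amplicon_max`` is advisory: pairs exceeding it are flagged,
    not rejected, because a design may accept a longer amplicon when no
    shorter conserved region exists.
    """

    max_mismatches: int = 3
    end_clean_bases: int = 1
    max_degeneracy: int = 16
    length_min: int = 15
    length_max: int = 20
    max_tm_gap: float = 4.0
    forbid_indels: bool = True
    screen_hairpin: bool = True
    screen_self_dimer: bool = True
    target_amplicon_max: int = 550

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        for name in ("max_mismatches", "end_clean_bases", "max_degeneracy",
                     "length_min", "length_max", "target_amplicon_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class ConsensusError(ValueError):
    """Raised when a window cannot yield an admissible consensus."""


def consensus_degenerate(
    window_sequences: list[str],
    max_degeneracy: int | None = None,
    minor_allele_threshold: float = 0.0,
) -> DegenerateOligo:
    """Minimal IUPAC consensus covering all observed bases, column-wise.

    Each column's code is the smallest IUPAC set containing every base seen
    there.  With ``minor_allele_threshold`` > 0, bases observed in at most
    that fraction of sequences are ignored (real databases contain
    sequencing errors; the default 0 is the strict full set cover).  Fails
    with :class:`ConsensusError` if the product degeneracy exceeds
    ``max_degeneracy`` or a gap is present.
    """
    if not window_sequences:
        raise ValueError("no window sequences")
    lengths = {len(s) for s in window_sequences}
    if len(lengths) > 1:
        raise ValueError(f"unequal window lengths: {sorted(lengths)}")
    n = len(window_sequences)
    codes = []
    for col in range(lengths.pop()):
        counts: dict[str, int] = {}
        for s in window_sequences:
            ch = s[col].upper()
            if ch == "-":
                raise ConsensusError(f"alignment gap at window column {col + 1}")
            counts[ch] = counts.get(ch, 0) + 1
        bases: set[str] = set()
        for code, k in counts.items():
            if minor_allele_threshold > 0 and k / n <= minor_allele_threshold:
                continue
            bases |= IUPAC_SETS[code]
        if not bases:  # everything fell below the minor-allele cut
            for code in counts:
                bases |= IUPAC_SETS[code]
        codes.append(SET_TO_CODE[frozenset(bases)])
    oligo = DegenerateOligo(name="consensus", sequence="".join(codes))
    if max_degeneracy is not None:
        d = degeneracy(oligo)
        if d > max_degeneracy:
            raise ConsensusError(
                f"consensus degeneracy {d} exceeds cap {max_degeneracy}"
            )
    return oligo


@dataclass(frozen=True)
class CandidatePrimer:
    """A consensus oligo over an alignment window, with its criterion audit.

    ``window_start``/``window_end`` are 1-based alignment columns.  The
    oligo carries gene coordinates equal to the window columns (valid when
    the alignment is gap-free over the targets, which criterion (vi)
    enforces).  ``criteria`` maps criterion keys to (passed, reason).
    """

    oligo: DegenerateOligo
    direction: str
    window_start: int
    window_end: int
    coverage: float
    criteria: dict[str, tuple[bool, str]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.criteria.values())


def evaluate_candidate(
    window_sequences: list[str],
    all_windows: dict[str, str],
    target_ids: set[str],
    direction: str,
    window_start: int,
    criteria: DesignCriteria,
) -> CandidatePrimer:
    """Build the consensus for one window and audit it against the criteria.

    ``all_windows`` maps every database record id to its (possibly gapped)
    window string; mismatches are counted per record against the consensus
    footprint, and a gap inside a target's window fails the indel
    criterion.  The audit is idempotent: re-evaluating an emitted candidate
    reproduces the same verdicts.
    """
    audit: dict[str, tuple[bool, str]] = {}
    width = len(window_sequences[0])
    gap_cols = sorted({
        i + 1
        for rid in target_ids
        for i, ch in enumerate(all_windows[rid])
        if ch == "-"
    })
    if gap_cols and criteria.forbid_indels:
        audit["indels"] = (False, f"gap in target record at column(s) {gap_cols}")
        consensus = None
    else:
        audit["indels"] = (True, "no indels among targets")
        try:
            consensus = consensus_degenerate([s.replace("-", "") for s in window_sequences])
        except (ConsensusError, ValueError) as exc:
            audit["degeneracy"] = (False, str(exc))
            consensus = None

    if consensus is None:
        oligo = DegenerateOligo(name="rejected", sequence="N" * width, direction=direction)
        return CandidatePrimer(oligo, direction, window_start,
                               window_start + width - 1, 0.0, audit)

    d = degeneracy(consensus)
    audit["degeneracy"] = (d <= criteria.max_degeneracy,
                           f"degeneracy {d} (cap {criteria.max_degeneracy})")
    footprint = consensus.sequence
    seq = footprint if direction == "forward" else reverse_complement(footprint)
    oligo = DegenerateOligo(
        name=f"cand_{direction[0]}_{window_start}",
        sequence=seq,
        direction=direction,
        gene_start=window_start,
        gene_end=window_start + width - 1,
    )

    # (i) mismatches against every target record
    n_cov = 0
    worst = 0
    for rid in sorted(target_ids):
        w = all_windows[rid]
        mm = width if "-" in w else count_mismatches(footprint, w)
        worst = max(worst, mm)
        if mm <= criteria.max_mismatches:
            n_cov += 1
    coverage = n_cov / len(target_ids)
    audit["mismatches"] = (coverage == 1.0,
                           f"max target mismatches {worst}, coverage {coverage:.2f}")

    # (ii) clean ends — checked on the synthesized orientation
    ends = end_check(oligo, n=criteria.end_clean_bases)
    audit["ends"] = (ends.five_prime_clean and ends.three_prime_clean,
                     f"5'={'clean' if ends.five_prime_clean else 'ambiguous'}, "
                     f"3'={'clean' if ends.three_prime_clean else 'ambiguous'}")

    # (iv) length by construction
    audit["length"] = (criteria.length_min <= width <= criteria.length_max,
                       f"length {width}")

    # (vii) secondary structure
    if criteria.screen_hairpin:
        hp = hairpin_screen(oligo)
        audit["hairpin"] = (not hp, f"{len(hp)} hairpin stem(s)")
    if criteria.screen_self_dimer:
        sd = self_dimer_screen(oligo)
        audit["self_dimer"] = (not sd.flagged, f"{len(sd.findings)} dimer run(s)")

    return CandidatePrimer(oligo, direction, window_start,
                           window_start + width - 1, coverage, audit)


def scan_candidates(
    db: ReferenceDB,
    target_groups: list[str],
    criteria: DesignCriteria = DesignCriteria(),
    direction: str = "forward",
    group_level: str = "clade",
    keep_failures: bool = False,
) -> list[CandidatePrimer]:
    """Slide windows over an aligned database and emit admissible candidates.

    Windows of every length in [length_min, length_max] are evaluated at
    every alignment column; the consensus is built over the records of
    ``target_groups`` and audited against the full criterion set (Tm
    pairing, criterion (v), is deferred to :func:`pair_candidates`).
    Candidates are sorted by (coverage desc, degeneracy asc, column asc);
    ties therefore resolve toward the least degenerate, leftmost window.
    """
    if not db.aligned:
        raise ValueError("scan_candidates requires an aligned ReferenceDB")
    if not target_groups:
        raise ValueError("no target groups given")
    groups = db.groups(group_level)
    unknown = [g for g in target_groups if g not in groups]
    if unknown:
        raise ValueError(f"unknown target group(s): {', '.join(unknown)}")
    target_ids = {r.id for g in target_groups for r in groups[g]}
    by_id = {r.id: r.sequence for r in db.records}
    aln_len = db.alignment_length or 0

    out = []
    for width in range(criteria.length_min, criteria.length_max + 1):
        for start in range(1, aln_len - width + 2):
            windows = {rid: s[start - 1:start - 1 + width] for rid, s in by_id.items()}
            target_windows = [windows[rid] for rid in sorted(target_ids)]
            cand = evaluate_candidate(
                target_windows, windows, target_ids, direction, start, criteria
            )
            if cand.passed or keep_failures:
                out.append(cand)
    return sorted(
        out,
        key=lambda c: (-c.coverage, degeneracy(c.oligo), c.window_start, c.window_end),
    )


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer combination with its expected amplicon."""

    forward: DegenerateOligo
    reverse: DegenerateOligo
    amplicon_start: int
    amplicon_end: int
    tm_gap: float
    exceeds_target_length: bool = False

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start + 1

    def __post_init__(self) -> None:
        if self.forward.direction != "forward" or self.reverse.direction != "reverse":
            raise ValueError("pair must be (forward, reverse)")


def make_pair(forward: DegenerateOligo, reverse: DegenerateOligo,
              tm_rule: str = "wallace") -> PrimerPair:
    """Assemble a coordinate-annotated pair; requires gene positions on both."""
    if forward.gene_start is None or reverse.gene_end is None:
        raise ValueError("both primers need gene coordinates")
    if reverse.gene_start <= forward.gene_end:
        raise ValueError(
            f"reverse footprint {reverse.gene_start}-{reverse.gene_end} is not "
            f"downstream of forward footprint {forward.gene_start}-{forward.gene_end}"
        )
    gap = abs(tm_estimate(forward, tm_rule).mean - tm_estimate(reverse, tm_rule).mean)
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        amplicon_start=forward.gene_start,
        amplicon_end=reverse.gene_end,
        tm_gap=gap,
    )


def pair_candidates(
    forwards: list[CandidatePrimer | DegenerateOligo],
    reverses: list[CandidatePrimer | DegenerateOligo],
    criteria: DesignCriteria = DesignCriteria(),
    amplicon_min: int = 100,
    amplicon_max: int = 1000,
    tm_rule: str = "wallace",
) -> list[PrimerPair]:
    """Enumerate admissible (forward, reverse) pairs.

    Keeps pairs with correct orientation, amplicon length (primers
    included) within [amplicon_min, amplicon_max] and Tm gap at most
    ``criteria.max_tm_gap``; pairs longer than
    ``criteria.target_amplicon_max`` are kept but flagged.  Sorted by
    combined coverage (desc) then amplicon length (asc).
    """
    def unwrap(c):
        return (c.oligo, c.coverage) if isinstance(c, CandidatePrimer) else (c, 1.0)

    pairs = []
    for fc in forwards:
        f, f_cov = unwrap(fc)
        for rc in reverses:
            r, r_cov = unwrap(rc)
            if f.gene_start is None or r.gene_end is None:
                raise ValueError("candidates must carry gene coordinates")
            if r.gene_start <= f.gene_end:
                continue
            length = r.gene_end - f.gene_start + 1
            if not (amplicon_min <= length <= amplicon_max):
                continue
            gap = abs(tm_estimate(f, tm_rule).mean - tm_estimate(r, tm_rule).mean)
            if gap > criteria.max_tm_gap:
                continue
            pairs.append(
                (
                    f_cov + r_cov,
                    replace(
                        make_pair(f, r, tm_rule),
                        exceeds_target_length=length > criteria.target_amplicon_max,
                    ),
                )
            )
    pairs.sort(key=lambda t: (-t[0], t[1].amplicon_length, t[1].amplicon_start))
    return [p for _, p in pairs]


@dataclass(frozen=True)
class NestedVerdict:
    classification: str  # nested | semi-nested | invalid
    ok: bool
    reasons: list[str]


def nested_compatibility(
    outer: PrimerPair,
    inner: PrimerPair,
    min_offset: int = 5,
    max_total_degeneracy: int | None = None,
) -> NestedVerdict:
    """Classify an (outer, inner) pair combination for nested PCR.

    Valid when both inner footprints lie within the outer amplicon and each
    inner primer is either identical to the same-direction outer primer
    (shared, as in semi-nested designs) or internal by at least
    ``min_offset`` bases.  Fully nested = both inner primers are new and
    internal; semi-nested = exactly one side shared.  Sharing both sides
    adds no specificity and is invalid.
    """
    reasons = []
    f_in, r_in = inner.forward, inner.reverse
    if not (outer.amplicon_start <= f_in.gene_start
            and r_in.gene_end <= outer.amplicon_end):
        reasons.append(
            f"inner footprints {f_in.gene_start}-{r_in.gene_end} extend outside "
            f"outer amplicon {outer.amplicon_start}-{outer.amplicon_end}"
        )
    f_shared = (f_in.sequence == outer.forward.sequence
                and f_in.gene_start == outer.forward.gene_start)
    r_shared = (r_in.sequence == outer.reverse.sequence
                and r_in.gene_end == outer.reverse.gene_end)
    f_internal = f_in.gene_start >= outer.forward.gene_start + min_offset
    r_internal = r_in.gene_end <= outer.reverse.gene_end - min_offset
    if not (f_shared or f_internal):
        reasons.append(
            f"inner forward at {f_in.gene_start} is neither shared with nor "
            f">= {min_offset} bases internal to the outer forward"
        )
    if not (r_shared or r_internal):
        reasons.append(
            f"inner reverse at {r_in.gene_end} is neither shared with nor "
            f">= {min_offset} bases internal to the outer reverse"
        )
    if f_shared and r_shared:
        reasons.append("inner pair identical to outer pair: no added specificity")
    if max_total_degeneracy is not None:
        total = degeneracy(f_in) * degeneracy(r_in)
        if total > max_total_degeneracy:
            reasons.append(f"inner degeneracy product {total} > {max_total_degeneracy}")
    if reasons:
        return NestedVerdict("invalid", False, reasons)
    if f_shared or r_shared:
        return NestedVerdict("semi-nested", True, [])
    return NestedVerdict("nested", True, [])
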