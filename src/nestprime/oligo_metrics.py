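"""Physical and combinatorial properties of a single oligo.

Degeneracy, ambiguity-weighted GC%, melting-temperature estimates, and the
secondary-structure screens (hairpin, self-dimer) plus terminal-ambiguity
checks used as primer design criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from nestprime.seqcore import (
    IUPAC_SETS,
    DegenerateOligo,
    normalize_sequence,
)

_GC = frozenset("GC")


def _seq(oligo: DegenerateOligo | str) -> str:
    return oligo.sequence if isinstance(oligo, DegenerateOligo) else normalize_sequence(oligo)


def degeneracy(oligo: DegenerateOligo | str) -> int:
    """Number of distinct plain sequences the oligo represents.

    The product over positions of the IUPAC base-set sizes; equals
    ``len(expand_degenerate(oligo))``.  A plain oligo has degeneracy 1
    (reporting layers that mimic the published table convention map 1 to 0
    for non-degenerate primers).
    """
    return math.prod(len(IUPAC_SETS[c]) for c in _seq(oligo))


def gc_percent(oligo: DegenerateOligo | str) -> float:
    """Ambiguity-weighted GC content in percent.

    A degenerate code contributes the fraction of its base set that is G or
    C (Y -> 0.5, V -> 2/3, N -> 0.5), so the result equals the mean plain
    GC% over all expansions.
    """
    seq = _seq(oligo)
    weight = sum(len(IUPAC_SETS[c] & _GC) / len(IUPAC_SETS[c]) for c in seq)
    return 100.0 * weight / len(seq)


@dataclass(frozen=True)
class TmEstimate:
    """Melting-temperature estimate aggregated over all oligo expansions."""

    mean: float
    min: float
    max: float

    @property
    def range(self) -> tuple[float, float]:
        return (self.min, self.max)


def tm_estimate(oligo: DegenerateOligo | str, rule: str = "wallace") -> TmEstimate:
    """Estimate Tm (degrees C) under a simple counting rule.

    rule='wallace': 2*(A+T) + 4*(G+C), the classic short-oligo rule.
    rule='basic_gc': 64.9 + 41*(GC - 16.4)/N.

    Degenerate positions are handled analytically: both rules are linear in
    the GC count, so the mean over expansions equals the rule applied to
    the ambiguity-weighted GC count, and min/max come from the per-position
    minimal/maximal GC contributions.
    """
    seq = _seq(oligo)
    n = len(seq)
    gc_mean = sum(len(IUPAC_SETS[c] & _GC) / len(IUPAC_SETS[c]) for c in seq)
    gc_min = sum(1.0 if IUPAC_SETS[c] <= _GC else 0.0 for c in seq)
    gc_max = sum(1.0 if IUPAC_SETS[c] & _GC else 0.0 for c in seq)
    if rule == "wallace":
        def f(gc: float) -> float:
            return 2.0 * (n - gc) + 4.0 * gc
    elif rule == "basic_gc":
        def f(gc: float) -> float:
            return 64.9 + 41.0 * (gc - 16.4) / n
    else:
        raise ValueError(f"unknown Tm rule {rule!r} (use 'wallace' or 'basic_gc')")
    return TmEstimate(mean=f(gc_mean), min=f(gc_min), max=f(gc_max))


def _complementary(a: str, b: str) -> bool:
    """IUPAC codes a, b can form a Watson-Crick pair in some expansion."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return any(comp[x] in IUPAC_SETS[b] for x in IUPAC_SETS[a])


@dataclass(frozen=True)
class HairpinFinding:
    """A pair of in-oligo segments that can fold back on each other.

    Positions are 1-based starts of the 5' and 3' stem arms; the 3' arm
    pairs with the 5' arm in reverse orientation.
    """

    stem5_start: int
    stem3_start: int
    stem_length: int
    loop_length: int


def hairpin_screen(
    oligo: DegenerateOligo | str,
    min_stem: int = 4,
    loop_min: int = 3,
    loop_max: int = 12,
) -> list[HairpinFinding]:
    """Find self-folding stems: reverse-complementary in-oligo segment pairs.

    Reports every maximal pair of segments of length >= ``min_stem`` whose
    bases are pairwise complementary in antiparallel orientation and whose
    separating loop lies within [loop_min, loop_max].  Degenerate positions
    count as complementary if any expansion pair is Watson-Crick (a
    conservative screen).  An empty list means the oligo passes.
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    if loop_min < 3:
        raise ValueError("loop_min must be >= 3 (shorter loops cannot form)")
    seq = _seq(oligo)
    n = len(seq)
    findings = []
    # i, j are 0-based starts of the 5' and 3' arms of a candidate stem of
    # length L: seq[i + k] pairs with seq[j + L - 1 - k].
    for i in range(n):
        for j in range(i + 1, n):
            for length in range(min_stem, n + 1):
                if j + length > n:
                    break
                loop = j - (i + length)
                if loop < loop_min or loop > loop_max:
                    continue
                if all(
                    _complementary(seq[i + k], seq[j + length - 1 - k])
                    for k in range(length)
                ):
                    findings.append(
                        HairpinFinding(
                            stem5_start=i + 1,
                            stem3_start=j + 1,
                            stem_length=length,
                            loop_length=loop,
                        )
                    )
    return _maximal_hairpins(findings)


def _maximal_hairpins(findings: list[HairpinFinding]) -> list[HairpinFinding]:
    """Drop findings whose stem is contained in a longer stem at the same fold."""
    keep = []
    for f in findings:
        contained = any(
            g is not f
            and g.stem_length > f.stem_length
            and g.stem5_start <= f.stem5_start
            and g.stem3_start <= f.stem3_start
            and g.stem5_start + g.stem_length >= f.stem5_start + f.stem_length
            and g.stem3_start + g.stem_length >= f.stem3_start + f.stem_length
            # same fold axis: the pairing midpoint is preserved
            and (g.stem5_start + g.stem3_start + g.stem_length
                 == f.stem5_start + f.stem3_start + f.stem_length)
            for g in findings
        )
        if not contained:
            keep.append(f)
    return sorted(keep, key=lambda f: (f.stem5_start, f.stem3_start, -f.stem_length))


@dataclass(frozen=True)
class DimerFinding:
    """A maximal complementary run between two antiparallel copies of the oligo.

    ``pos_a``/``pos_b`` are 1-based starts of the run on the two copies
    (the run on copy B pairs in reverse), ``involves_3prime`` marks runs
    touching the 3'-terminal window of either copy.
    """

    pos_a: int
    pos_b: int
    run_length: int
    involves_3prime: bool


@dataclass(frozen=True)
class DimerReport:
    findings: list[DimerFinding] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.findings)


def self_dimer_screen(
    oligo: DegenerateOligo | str,
    min_run: int = 8,
    three_prime_window: int = 5,
    three_prime_min_run: int = 4,
) -> DimerReport:
    """Screen for self-dimerization between two copies of the oligo.

    Aligns the oligo against itself in antiparallel orientation at every
    offset and finds maximal contiguous complementary runs.  A run is
    flagged when it reaches ``min_run`` anywhere, or ``three_prime_min_run``
    while involving the 3'-terminal ``three_prime_window`` bases of either
    copy (3'-anchored dimers prime extension and are the dangerous case).
    """
    if min_run < 3:
        raise ValueError("min_run must be >= 3")
    seq = _seq(oligo)
    n = len(seq)
    findings = []
    # Antiparallel alignment: position i on copy A pairs with position j on
    # copy B where i + j = c (constant per register).
    for c in range(0, 2 * n - 1):
        run_start = None
        i_lo = max(0, c - (n - 1))
        i_hi = min(n - 1, c)
        for i in range(i_lo, i_hi + 2):
            j = c - i
            paired = i <= i_hi and _complementary(seq[i], seq[j])
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                findings.extend(
                    _classify_run(run_start, i - run_start, c, n,
                                  min_run, three_prime_window, three_prime_min_run)
                )
                run_start = None
    return DimerReport(findings=sorted(findings, key=lambda f: (f.pos_a, f.pos_b)))


def _classify_run(
    start: int, length: int, c: int, n: int,
    min_run: int, window: int, window_min_run: int,
) -> list[DimerFinding]:
    i_end = start + length - 1
    j_start = c - i_end
    # 3' end of copy A is position n-1; of copy B (read on its own strand)
    # also n-1.  The run covers A positions [start, i_end] and B positions
    # [j_start, c - start].
    involves_3p = (i_end >= n - window) or (c - start >= n - window)
    flag = length >= min_run or (involves_3p and length >= window_min_run)
    if not flag:
        return []
    return [DimerFinding(pos_a=start + 1, pos_b=j_start + 1,
                         run_length=length, involves_3prime=involves_3p)]


@dataclass(frozen=True)
class EndCheck:
    five_prime_clean: bool
    three_prime_clean: bool


def end_check(oligo: DegenerateOligo | str, n: int = 1) -> EndCheck:
    """True per end iff the terminal ``n`` bases carry no degenerate code."""
    seq = _seq(oligo)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(seq):
        raise ValueError(f"terminal window {n} >= oligo length {len(seq)}")
    plain = set("ACGT")
    return EndCheck(
        five_prime_clean=all(c in plain for c in seq[:n]),
        three_prime_clean=all(c in plain for c in seq[-n:]),
    )


@dataclass(frozen=True)
class OligoReport:
    """Summary of the per-oligo metrics used in design reports."""

    name: str
    length: int
    degeneracy: int
    gc_percent: float
    tm: TmEstimate
    hairpins: list[HairpinFinding]
    self_dimers: DimerReport
    ends: EndCheck

    @property
    def hairpin_flag(self) -> bool:
        return bool(self.hairpins)

    @property
    def dimer_flag(self) -> bool:
        return self.self_dimers.flagged


def oligo_report(
    oligo: DegenerateOligo,
    tm_rule: str = "wallace",
    hairpin_min_stem: int = 4,
    dimer_min_run: int = 8,
    end_bases: int = 1,
) -> OligoReport:
    """Compute the full metric panel for one oligo."""
    return OligoReport(
        name=oligo.name,
        length=len(oligo),
        degeneracy=degeneracy(oligo),
        gc_percent=gc_percent(oligo),
        tm=tm_estimate(oligo, rule=tm_rule),
        hairpins=hairpin_screen(oligo, min_stem=hairpin_min_stem),
        self_dimers=self_dimer_screen(oligo, min_run=dimer_min_run),
        ends=end_check(oligo, n=end_bases),
    )
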