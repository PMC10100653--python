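"""IUPAC-aware primer-to-template matching.

Mismatch counting between degenerate windows, binding-site discovery on
both strands, and per-taxon mismatch/coverage profiles against a reference
database.  A position is a mismatch iff the primer code's base set and the
template code's base set are disjoint (so N is compatible with anything);
this equals the minimum plain Hamming distance over all expansion pairs and
never rejects a feasible duplex when references carry ambiguity codes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from nestprime.seqcore import (
    IUPAC_SETS,
    DegenerateOligo,
    ReferenceDB,
    ReferenceRecord,
    normalize_sequence,
)


def count_mismatches(primer_window: str, template_window: str) -> int:
    """Mismatches between two equal-length IUPAC strings.

    Counts positions whose base sets are disjoint; equals the minimum
    Hamming distance over all pairs of plain expansions.
    """
    p = normalize_sequence(primer_window)
    t = normalize_sequence(template_window)
    if len(p) != len(t):
        raise ValueError(f"window lengths differ: {len(p)} vs {len(t)}")
    return sum(1 for a, b in zip(p, t) if IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b]))


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on a template.

    ``start``/``end`` are 1-based inclusive on the template forward strand;
    ``strand`` is the primer's orientation.  For a reverse-strand site the
    primer's 3' terminus sits at ``start`` on the forward strand.
    """

    template_id: str
    strand: str  # forward | reverse
    start: int
    end: int
    mismatches: int
    three_prime_terminal_match: bool

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad site coordinates {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_binding_sites(
    primer: DegenerateOligo,
    template: ReferenceRecord | str,
    max_mismatches: int = 3,
    require_3prime_match: bool = False,
) -> list[BindingSite]:
    """Scan a template for primer binding sites within a mismatch tolerance.

    Forward primers are matched on the forward strand; reverse primers are
    matched as their reverse-complement footprint on the forward strand
    (equivalently, direct matching on the reverse strand).  When
    ``require_3prime_match`` is set, sites whose 3'-terminal primer base
    mismatches the template are discarded (a 3' mismatch generally kills
    polymerase extension).  Sites are sorted by (mismatches, start).
    """
    if isinstance(template, ReferenceRecord):
        tmpl_id, tmpl_seq = template.id, template.ungapped
    else:
        tmpl_id, tmpl_seq = "template", normalize_sequence(template)
    probe = primer.forward_footprint
    m = len(probe)
    if len(tmpl_seq) < m:
        return []
    sites = []
    # index of the primer's 3'-terminal base within the forward footprint
    three_prime_idx = m - 1 if primer.direction == "forward" else 0
    for off in range(len(tmpl_seq) - m + 1):
        window = tmpl_seq[off:off + m]
        mm = count_mismatches(probe, window)
        if mm > max_mismatches:
            continue
        tp_ok = not IUPAC_SETS[probe[three_prime_idx]].isdisjoint(
            IUPAC_SETS[window[three_prime_idx]]
        )
        if require_3prime_match and not tp_ok:
            continue
        sites.append(
            BindingSite(
                template_id=tmpl_id,
                strand=primer.direction,
                start=off + 1,
                end=off + m,
                mismatches=mm,
                three_prime_terminal_match=tp_ok,
            )
        )
    return sorted(sites, key=lambda s: (s.mismatches, s.start))


def best_site(
    primer: DegenerateOligo,
    template: ReferenceRecord | str,
    max_mismatches: int,
    require_3prime_match: bool = False,
) -> BindingSite | None:
    """Lowest-mismatch site, ties broken by leftmost start; None if absent."""
    sites = find_binding_sites(primer, template, max_mismatches, require_3prime_match)
    return sites[0] if sites else None


@dataclass(frozen=True)
class TaxonProfile:
    """Best-site mismatch distribution of one primer over one taxon group."""

    group: str
    n_records: int
    n_with_site: int
    min_mismatches: int | None
    median_mismatches: float | None
    max_mismatches: int | None
    coverage: float  # fraction of records with best site <= threshold
    threshold: int


def taxon_profile(
    primer: DegenerateOligo,
    db: ReferenceDB,
    group_level: str = "clade",
    max_mismatches: int = 3,
    search_bound: int | None = None,
) -> list[TaxonProfile]:
    """Per-group mismatch profile of a primer against a reference database.

    For each record the best binding site is found under a relaxed search
    bound (default ``max_mismatches + 3``, so near-misses are still
    quantified); ``coverage`` is the fraction of the group's records whose
    best site has at most ``max_mismatches`` mismatches.  Records with no
    site under the search bound count as uncovered and are excluded from
    the min/median/max statistics.
    """
    if not db.records:
        raise ValueError("empty reference database")
    bound = search_bound if search_bound is not None else max_mismatches + 3
    profiles = []
    for group, records in sorted(db.groups(group_level).items()):
        best = [best_site(primer, r, bound) for r in records]
        mms = sorted(s.mismatches for s in best if s is not None)
        covered = sum(1 for s in best if s is not None and s.mismatches <= max_mismatches)
        profiles.append(
            TaxonProfile(
                group=group,
                n_records=len(records),
                n_with_site=len(mms),
                min_mismatches=mms[0] if mms else None,
                median_mismatches=statistics.median(mms) if mms else None,
                max_mismatches=mms[-1] if mms else None,
                coverage=covered / len(records),
                threshold=max_mismatches,
            )
        )
    return profiles


@dataclass(frozen=True)
class SpecificityReport:
    """Inclusion/exclusion verdict of a primer over target and off-target groups."""

    passed: bool
    include_profiles: list[TaxonProfile]
    exclude_profiles: list[TaxonProfile]
    failures: list[str]


def specificity_report(
    primer: DegenerateOligo,
    db: ReferenceDB,
    include_groups: list[str],
    exclude_groups: list[str] | None = None,
    group_level: str = "subcluster",
    k_include: int = 0,
    k_exclude: int = 2,
    min_include_fraction: float = 1.0,
) -> SpecificityReport:
    """Check that a primer covers its targets and excludes off-targets.

    Pass iff every include group has at least ``min_include_fraction`` of
    records with best site <= ``k_include`` mismatches, AND every exclude
    group has ALL records at > ``k_exclude`` mismatches (the default
    ``k_exclude=2`` makes "excluded" mean >= 3 mismatches).
    """
    exclude_groups = exclude_groups or []
    groups = db.groups(group_level)
    unknown = [g for g in include_groups + exclude_groups if g not in groups]
    if unknown:
        raise ValueError(f"unknown group(s) at level {group_level!r}: {', '.join(unknown)}")

    failures: list[str] = []
    inc_profiles = []
    for g in include_groups:
        prof = _profile_one(primer, groups[g], g, k_include)
        inc_profiles.append(prof)
        if prof.coverage < min_include_fraction:
            bad = [
                r.id for r in groups[g]
                if (s := best_site(primer, r, k_include + 3)) is None
                or s.mismatches > k_include
            ]
            failures.append(
                f"include group {g!r}: coverage {prof.coverage:.2f} < "
                f"{min_include_fraction:.2f} (offending: {', '.join(bad)})"
            )
    exc_profiles = []
    for g in exclude_groups:
        prof = _profile_one(primer, groups[g], g, k_exclude)
        exc_profiles.append(prof)
        if prof.coverage > 0:
            hit = [
                r.id for r in groups[g]
                if (s := best_site(primer, r, k_exclude)) is not None
            ]
            failures.append(
                f"exclude group {g!r}: {len(hit)} record(s) within "
                f"{k_exclude} mismatches ({', '.join(hit)})"
            )
    return SpecificityReport(
        passed=not failures,
        include_profiles=inc_profiles,
        exclude_profiles=exc_profiles,
        failures=failures,
    )


def _profile_one(
    primer: DegenerateOligo, records: list[ReferenceRecord], group: str, threshold: int
) -> TaxonProfile:
    best = [best_site(primer, r, threshold + 3) for r in records]
    mms = sorted(s.mismatches for s in best if s is not None)
    covered = sum(1 for s in best if s is not None and s.mismatches <= threshold)
    return TaxonProfile(
        group=group,
        n_records=len(records),
        n_with_site=len(mms),
        min_mismatches=mms[0] if mms else None,
        median_mismatches=statistics.median(mms) if mms else None,
        max_mismatches=mms[-1] if mms else None,
        coverage=covered / len(records),
        threshold=threshold,
    )
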