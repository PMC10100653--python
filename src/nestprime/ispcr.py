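"""In-silico PCR: single-round and nested amplification.

An amplicon spans from the 5' end of the forward-primer footprint to the 3'
end of the reverse-primer footprint on the template forward strand, primers
included; the insert is the region strictly between the footprints.
Round-2 products of a nested reaction are generated only from round-1
product sequences and carry coordinates mapped back to the original
template, so nesting is a real containment contract, not a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

from nestprime.binding import BindingSite, find_binding_sites
from nestprime.design import PrimerPair
from nestprime.seqcore import DegenerateOligo, ReferenceRecord, normalize_sequence


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product with its primer sites.

    ``start``/``end`` are 1-based inclusive on the original template
    forward strand (for round-2 products, mapped through the parent).
    """

    template_id: str
    round: int
    start: int
    end: int
    sequence: str
    fwd_site: BindingSite
    rev_site: BindingSite
    parent: "Amplicon | None" = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"amplicon length {len(self.sequence)} != span "
                f"{self.end}-{self.start}+1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def amplify(
    template: ReferenceRecord | str,
    fwd: DegenerateOligo,
    rev: DegenerateOligo,
    max_mismatches: int = 3,
    require_3prime_match: bool = True,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Predict all products of one primer pair on one (ungapped) template.

    Every combination of a forward site and a downstream, non-overlapping
    reverse site with product length <= ``max_product`` yields one
    amplicon.  Results are ordered by (start, length).  Circular templates
    are not supported.
    """
    if isinstance(template, ReferenceRecord):
        tmpl_id, seq = template.id, template.ungapped
    else:
        tmpl_id, seq = "template", normalize_sequence(template)
    if fwd.direction != "forward" or rev.direction != "reverse":
        raise ValueError("amplify needs a forward and a reverse primer")
    f_sites = find_binding_sites(fwd, seq, max_mismatches, require_3prime_match)
    r_sites = find_binding_sites(rev, seq, max_mismatches, require_3prime_match)
    products = []
    for fs in f_sites:
        for rs in r_sites:
            if rs.start <= fs.end:
                continue
            length = rs.end - fs.start + 1
            if length > max_product:
                continue
            products.append(
                Amplicon(
                    template_id=tmpl_id,
                    round=1,
                    start=fs.start,
                    end=rs.end,
                    sequence=seq[fs.start - 1:rs.end],
                    fwd_site=BindingSite(tmpl_id, "forward", fs.start, fs.end,
                                         fs.mismatches, fs.three_prime_terminal_match),
                    rev_site=BindingSite(tmpl_id, "reverse", rs.start, rs.end,
                                         rs.mismatches, rs.three_prime_terminal_match),
                )
            )
    return sorted(products, key=lambda a: (a.start, a.length))


def nested_amplify(
    template: ReferenceRecord | str,
    round1: PrimerPair | tuple[DegenerateOligo, DegenerateOligo],
    round2: PrimerPair | tuple[DegenerateOligo, DegenerateOligo],
    max_mismatches: int = 3,
    require_3prime_match: bool = True,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Two-round nested PCR: round 2 amplifies round-1 products only.

    Round-2 primers that bind the original template outside a round-1
    product yield nothing, mirroring the wet-lab protocol where the second
    reaction receives first-round product as its sole template.  Emitted
    amplicons have ``round == 2``, a ``parent`` link, and coordinates on
    the original template.
    """
    f1, r1 = _unpack(round1)
    f2, r2 = _unpack(round2)
    products = []
    for parent in amplify(template, f1, r1, max_mismatches,
                          require_3prime_match, max_product):
        for inner in amplify(parent.sequence, f2, r2, max_mismatches,
                             require_3prime_match, max_product):
            offset = parent.start - 1
            fs, rs = inner.fwd_site, inner.rev_site
            products.append(
                Amplicon(
                    template_id=parent.template_id,
                    round=2,
                    start=inner.start + offset,
                    end=inner.end + offset,
                    sequence=inner.sequence,
                    fwd_site=BindingSite(parent.template_id, "forward",
                                         fs.start + offset, fs.end + offset,
                                         fs.mismatches, fs.three_prime_terminal_match),
                    rev_site=BindingSite(parent.template_id, "reverse",
                                         rs.start + offset, rs.end + offset,
                                         rs.mismatches, rs.three_prime_terminal_match),
                    parent=parent,
                )
            )
    return sorted(products, key=lambda a: (a.start, a.length))


def _unpack(pair) -> tuple[DegenerateOligo, DegenerateOligo]:
    if isinstance(pair, PrimerPair):
        return pair.forward, pair.reverse
    f, r = pair
    return f, r


def trim_primers(amplicon: Amplicon) -> tuple[str, int, int]:
    """Remove both primer footprints, returning (insert, start, end).

    Coordinates are 1-based inclusive on the original template; the insert
    is the region strictly between the footprints and may be empty when the
    primers are adjacent.  Overlapping footprints are rejected.
    """
    ins_start = amplicon.fwd_site.end + 1
    ins_end = amplicon.rev_site.start - 1
    if ins_end < ins_start - 1:
        raise ValueError(
            f"primer footprints overlap ({amplicon.fwd_site.start}-"
            f"{amplicon.fwd_site.end} vs {amplicon.rev_site.start}-"
            f"{amplicon.rev_site.end}); nothing to trim"
        )
    lo = ins_start - amplicon.start
    hi = ins_end - amplicon.start + 1
    return amplicon.sequence[lo:hi], ins_start, ins_end
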