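"""Deterministic synthetic reference databases, templates and ASV sets.

These generators make every other module testable without downloading a
real reference database.  They emulate the structure of a curated
marker-gene database for marine picocyanobacteria: a hierarchy of clades
and subclades diverging from a common ancestor under a uniform
(Jukes-Cantor-style) substitution model, with conserved windows planted
verbatim in all records so that primer-design scans have a known ground
truth.  No indels are simulated: the *petB* marker is highly conserved in
length, and the design criteria treat alignment gaps as disqualifying, so
the default fixture is gap-free (a gap-injection helper exists solely to
exercise that rejection path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nestprime.binding import find_binding_sites
from nestprime.petb import PETB_F, PETB_R, PETB_50F, PETB_634R, PETB_GENE_LENGTH
from nestprime.seqcore import (
    DegenerateOligo,
    ReferenceDB,
    ReferenceRecord,
    TaxonomyLabel,
    expand_degenerate,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic reference-database generator.

    Divergences are per-site substitution probabilities applied on the
    branch from the parent sequence; ``conserved_windows`` are (start, end,
    sequence) triples (1-based inclusive) restored verbatim in every record
    after mutation, guaranteeing shared primer-binding regions.
    """

    seed: int = 0
    n_clades: int = 3
    n_subclades_per_clade: int = 2
    n_records_per_subclade: int = 4
    between_clade_divergence: float = 0.15
    between_subclade_divergence: float = 0.06
    within_subclade_divergence: float = 0.02
    conserved_windows: tuple[tuple[int, int, str], ...] = ()
    gene_length: int = PETB_GENE_LENGTH
    subcluster: str = "5.1"

    def __post_init__(self) -> None:
        for name in ("between_clade_divergence", "between_subclade_divergence",
                     "within_subclade_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.75:
                raise ValueError(f"{name}={v} outside [0, 0.75]")
        spans = []
        for start, end, seq in self.conserved_windows:
            if not (1 <= start <= end <= self.gene_length):
                raise ValueError(f"window {start}-{end} outside gene of "
                                 f"length {self.gene_length}")
            if end - start + 1 != len(seq):
                raise ValueError(f"window {start}-{end} does not fit its sequence")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("conserved windows overlap")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform substitution: each site flips to one of the 3 other bases."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _plant(seq: np.ndarray, windows) -> np.ndarray:
    out = seq.copy()
    for start, end, wseq in windows:
        out[start - 1:end] = list(wseq.upper())
    return out


def make_reference_db(config: SimulationConfig) -> ReferenceDB:
    """Simulate a taxonomy-annotated reference database.

    A root sequence is drawn uniformly; clade ancestors mutate from the
    root, subclade ancestors from their clade ancestor, and records from
    their subclade ancestor, each at the configured per-site rate.
    Conserved windows are restored verbatim in every record, and the single
    column on each side of every planted window is forced to differ between
    clades (when there are at least two), so a planted window is the unique
    fully conserved region of its length and design scans have an
    unambiguous ground truth.  Records all
    have the same ungapped length (no indels), so the database is returned
    flagged as aligned and can feed the design scanner directly; use
    ``ReferenceDB(db.records, aligned=False)`` for an unaligned view.
    Byte-identical output per seed.
    """
    rng = np.random.default_rng(config.seed)
    root = rng.choice(_BASES, size=config.gene_length)
    records = []
    for c in range(config.n_clades):
        clade_name = f"clade{c + 1}"
        clade_anc = _mutate(root, config.between_clade_divergence, rng)
        for s in range(config.n_subclades_per_clade):
            subclade_name = f"{clade_name}{'abcdefghij'[s]}"
            sub_anc = _mutate(clade_anc, config.between_subclade_divergence, rng)
            for r in range(config.n_records_per_subclade):
                seq = _mutate(sub_anc, config.within_subclade_divergence, rng)
                seq = _plant(seq, config.conserved_windows)
                if config.n_clades > 1:
                    for start, end, _ in config.conserved_windows:
                        for col in (start - 1, end + 1):
                            if 1 <= col <= config.gene_length:
                                seq[col - 1] = "ACGT"[c % 4]
                records.append(
                    ReferenceRecord(
                        id=f"{subclade_name}_{r + 1:02d}",
                        sequence="".join(seq),
                        taxonomy=TaxonomyLabel(config.subcluster, clade_name,
                                               subclade_name),
                    )
                )
    return ReferenceDB(records, aligned=True)


def taxonomy_rows(db: ReferenceDB) -> list[str]:
    """Render a database's taxonomy as TSV lines (with header)."""
    lines = ["id\tsubcluster\tclade\tsubclade"]
    for r in db.records:
        t = r.taxonomy
        lines.append(f"{r.id}\t{t.subcluster}\t{t.clade}\t{t.subclade}")
    return lines


def inject_gap(db: ReferenceDB, record_index: int, column: int) -> ReferenceDB:
    """Replace one aligned column of one record with a gap (for indel tests)."""
    recs = list(db.records)
    r = recs[record_index]
    seq = r.sequence[:column - 1] + "-" + r.sequence[column:]
    recs[record_index] = ReferenceRecord(r.id, seq, r.taxonomy)
    return ReferenceDB(recs, aligned=True)


def make_benchmark_template(seed: int = 2022) -> ReferenceRecord:
    """A 657-bp template carrying perfect sites for the published primer sets.

    The template holds, at the published gene coordinates, one concrete
    expansion of each primer's forward-strand footprint: petB-F at 22-41,
    petB-50F at 50-66, petB-R at 601-618 and petB-634R at 615-634.  The
    petB-R and petB-634R footprints overlap at 615-618; both primers end in
    the same fixed bases there, so the overlap is consistent by
    construction.  Elsewhere the sequence is random but seeded.  The
    construction is verified internally: each primer must have exactly one
    zero-mismatch site, at its published coordinates.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = rng.choice(_BASES, size=PETB_GENE_LENGTH)
        placements = [
            (PETB_F.gene_start, PETB_F.gene_end, _one_expansion(PETB_F, rng)),
            (PETB_50F.gene_start, PETB_50F.gene_end, _one_expansion(PETB_50F, rng)),
            (PETB_R.gene_start, PETB_R.gene_end, _one_expansion(PETB_R, rng)),
        ]
        for start, end, footprint in placements:
            seq[start - 1:end] = list(footprint)
        # petB-634R (615-634) overlaps petB-R (601-618) at 615-618: keep the
        # bases already placed there and draw the rest from an expansion
        # compatible with them.
        r634 = _one_expansion(PETB_634R, rng)
        seq[618:PETB_634R.gene_end] = list(r634[4:])
        assert "".join(seq[614:618]) == r634[:4], "overlap bases must agree"
        record = ReferenceRecord(
            id="petB_benchmark_template",
            sequence="".join(seq),
            taxonomy=TaxonomyLabel("5.1", "benchmark", ""),
        )
        if _verify_unique_sites(record):
            return record
    raise RuntimeError("could not build a template with unique primer sites")


def _one_expansion(primer: DegenerateOligo, rng: np.random.Generator) -> str:
    """A deterministic concrete forward-strand footprint of a primer."""
    expansions = sorted(expand_degenerate(primer))
    chosen = expansions[rng.integers(len(expansions))]
    return chosen if primer.direction == "forward" else reverse_complement(chosen)


def _verify_unique_sites(record: ReferenceRecord) -> bool:
    expected = {
        PETB_F.name: (PETB_F.gene_start, PETB_F.gene_end),
        PETB_50F.name: (PETB_50F.gene_start, PETB_50F.gene_end),
        PETB_R.name: (PETB_R.gene_start, PETB_R.gene_end),
        PETB_634R.name: (PETB_634R.gene_start, PETB_634R.gene_end),
    }
    for primer in (PETB_F, PETB_50F, PETB_R, PETB_634R):
        sites = find_binding_sites(primer, record, max_mismatches=0)
        if len(sites) != 1:
            return False
        if (sites[0].start, sites[0].end) != expected[primer.name]:
            return False
    return True


@dataclass(frozen=True)
class SimulatedASV:
    id: str
    sequence: str
    assigned_group: str
    spurious: bool


@dataclass(frozen=True)
class ASVSimulation:
    """Simulated ASV set plus the generator's own bookkeeping."""

    asvs: list[SimulatedASV]
    n_spurious: int

    def as_assignment_triples(self) -> list[tuple[str, str, str]]:
        return [(a.id, a.sequence, a.assigned_group) for a in self.asvs]

    @property
    def true_correct_fraction(self) -> float:
        return 1.0 - self.n_spurious / len(self.asvs)


def simulate_asvs(
    amplicon_db: ReferenceDB,
    n_per_group: int = 20,
    error_rate: float = 0.01,
    spurious_fraction: float = 0.0,
    group_level: str = "clade",
    seed: int = 0,
) -> ASVSimulation:
    """Draw ASVs from group amplicons, with a known spurious fraction.

    Genuine ASVs are reference amplicons with per-site substitutions at
    ``error_rate``; spurious ASVs are uniformly random sequences of the
    same length carrying a genuine group label (mimicking off-target
    amplification products that a classifier mislabels).  The generator
    records exactly which ASVs are spurious, so validation statistics can
    be checked against its bookkeeping.  Deterministic per seed.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate outside [0, 0.2]")
    if not 0.0 <= spurious_fraction <= 1.0:
        raise ValueError("spurious_fraction outside [0, 1]")
    if not amplicon_db.records:
        raise ValueError("empty amplicon database")
    rng = np.random.default_rng(seed)
    groups = amplicon_db.groups(group_level)
    asvs: list[SimulatedASV] = []
    n_spurious = 0
    for group in sorted(groups):
        templates = groups[group]
        n_spur = int(round(spurious_fraction * n_per_group))
        for i in range(n_per_group):
            asv_id = f"asv_{group}_{i + 1:03d}"
            tmpl = templates[rng.integers(len(templates))]
            base = np.array(list(tmpl.ungapped))
            if i < n_spur:
                seq = "".join(rng.choice(_BASES, size=len(base)))
                asvs.append(SimulatedASV(asv_id, seq, group, spurious=True))
                n_spurious += 1
            else:
                seq = "".join(_mutate(base, error_rate, rng))
                asvs.append(SimulatedASV(asv_id, seq, group, spurious=False))
    return ASVSimulation(asvs=asvs, n_spurious=n_spurious)
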