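"""IUPAC sequence algebra, translation and reference-database I/O.

All other modules build on the primitives here: expansion of degenerate
(IUPAC-ambiguity) oligos into plain sequences, IUPAC-aware
reverse-complementation, bacterial-code translation, and loading of a
reference FASTA plus its taxonomy table into a :class:`ReferenceDB`.

Conventions
-----------
* Sequences are DNA, uppercase; ``U`` is accepted on input and normalized
  to ``T``, lowercase to uppercase.
* Coordinates are 1-based and inclusive on the gene-forward strand.
* Reverse primers are stored 5'->3' as synthesized, i.e. the
  reverse-complement of their forward-strand footprint; their
  ``gene_start``/``gene_end`` refer to that forward-strand footprint.
* The alignment gap character ``-`` is illegal inside a
  :class:`DegenerateOligo` and legal in a :class:`ReferenceDB` only when it
  is flagged as aligned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes mapped to the set of plain bases each represents.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: frozenset of bases -> IUPAC code.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def normalize_sequence(seq: str, allow_gaps: bool = False) -> str:
    """Uppercase a nucleotide string, map U->T, and validate IUPAC codes.

    Parameters
    ----------
    seq : raw nucleotide string.
    allow_gaps : permit the alignment gap character ``-``.

    Raises
    ------
    ValueError
        If the string is empty or contains a character that is not a valid
        IUPAC nucleotide code; the message names the offending 1-based
        position.
    """
    if not seq:
        raise ValueError("empty sequence")
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out, start=1):
        if ch in IUPAC_SETS:
            continue
        if ch == "-" and allow_gaps:
            continue
        raise ValueError(f"invalid IUPAC character {ch!r} at position {i}")
    return out


@dataclass(frozen=True)
class DegenerateOligo:
    """A primer: an IUPAC nucleotide string with orientation metadata.

    ``sequence`` is always written 5'->3' as synthesized.  For a reverse
    primer this is the reverse-complement of the gene-forward strand;
    ``gene_start``/``gene_end`` (1-based, inclusive) always refer to the
    footprint on the gene-forward strand.
    """

    name: str
    sequence: str
    direction: str = "forward"  # forward | reverse
    gene_start: int | None = None
    gene_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        if (self.gene_start is None) != (self.gene_end is None):
            raise ValueError("gene_start and gene_end must be set together")
        if self.gene_start is not None:
            span = self.gene_end - self.gene_start + 1
            if span != len(self.sequence):
                raise ValueError(
                    f"gene positions {self.gene_start}-{self.gene_end} span {span} "
                    f"but sequence has length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def forward_footprint(self) -> str:
        """The oligo's sequence on the gene-forward strand."""
        if self.direction == "forward":
            return self.sequence
        return reverse_complement(self.sequence)


@dataclass(frozen=True)
class TaxonomyLabel:
    """Three-level hierarchy label: subcluster -> clade -> subclade.

    Levels are compared case-sensitively after whitespace trimming;
    ``subclade`` may be empty (not every clade is subdivided).
    """

    subcluster: str = ""
    clade: str = ""
    subclade: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subcluster", self.subcluster.strip())
        object.__setattr__(self, "clade", self.clade.strip())
        object.__setattr__(self, "subclade", self.subclade.strip())

    def level(self, name: str) -> str:
        if name not in ("subcluster", "clade", "subclade"):
            raise ValueError(f"unknown taxonomy level {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence with its taxonomy label.

    The sequence may contain gaps only inside an aligned ReferenceDB.
    """

    id: str
    sequence: str
    taxonomy: TaxonomyLabel = field(default_factory=TaxonomyLabel)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, allow_gaps=True))

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    """A collection of reference records, optionally as a fixed alignment."""

    records: list[ReferenceRecord]
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {', '.join(dupes)}")
        if self.aligned:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise ValueError(
                    f"aligned database has unequal record lengths: {sorted(lengths)}"
                )
        else:
            for r in self.records:
                if "-" in r.sequence:
                    raise ValueError(f"gap character in unaligned record {r.id!r}")

    @property
    def alignment_length(self) -> int | None:
        if not self.aligned or not self.records:
            return None
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def groups(self, level: str) -> dict[str, list[ReferenceRecord]]:
        """Partition records by taxonomy level; unlabeled -> 'unassigned'."""
        out: dict[str, list[ReferenceRecord]] = {}
        for r in self.records:
            key = r.taxonomy.level(level) or "unassigned"
            out.setdefault(key, []).append(r)
        return out


def expand_degenerate(oligo: DegenerateOligo | str) -> set[str]:
    """Enumerate every plain-DNA sequence an IUPAC oligo represents.

    The result size equals the product of per-position base-set sizes
    (the oligo's degeneracy).  Raises ``ValueError`` on invalid characters.
    """
    seq = oligo.sequence if isinstance(oligo, DegenerateOligo) else normalize_sequence(oligo)
    pools = [sorted(IUPAC_SETS[c]) for c in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, B<->V, N<->N, ...)."""
    seq = normalize_sequence(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def codes_compatible(a: str, b: str) -> bool:
    """True if two IUPAC codes share at least one base (N matches all)."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def translate(nt: str, frame: int = 1) -> str:
    """Translate DNA with the bacterial/plastid genetic code (table 11).

    ``frame`` is 1, 2 or 3 (1-based offset into the sequence).  The
    incomplete trailing codon is dropped.  A codon containing degenerate
    bases translates to the unique amino acid if every expansion agrees,
    otherwise ``X``; a codon whose expansions are all stops yields ``*``.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    seq = normalize_sequence(nt)
    seq = seq[frame - 1:]
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aas.append(_translate_codon(seq[i:i + 3]))
    return "".join(aas)


def _translate_codon(codon: str) -> str:
    outcomes = set()
    for expansion in itertools.product(*(sorted(IUPAC_SETS[c]) for c in codon)):
        plain = "".join(expansion)
        if plain in _TABLE11.stop_codons:
            outcomes.add("*")
        else:
            outcomes.add(_TABLE11.forward_table[plain])
        if len(outcomes) > 1:
            return "X"
    return outcomes.pop()


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly wrapped) multi-record FASTA into (id, sequence) pairs.

    Duplicate ids are rejected.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs to FASTA (line-wrapped at 60 columns)."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLabel]:
    """Read a taxonomy TSV: header ``id<TAB>subcluster<TAB>clade<TAB>subclade``.

    The subclade field may be empty.  Duplicate ids are rejected.
    """
    path = Path(path)
    out: dict[str, TaxonomyLabel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:4]] != ["id", "subcluster", "clade", "subclade"]:
            raise ValueError(
                f"taxonomy file {path} must start with header "
                f"'id\\tsubcluster\\tclade\\tsubclade', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
            rec_id = fields[0].strip()
            if rec_id in out:
                raise ValueError(f"duplicate taxonomy id {rec_id!r} at {path}:{lineno}")
            subclade = fields[3] if len(fields) > 3 else ""
            out[rec_id] = TaxonomyLabel(fields[1], fields[2], subclade)
    return out


def load_reference_db(
    fasta_path: str | Path,
    taxonomy: str | Path | Mapping[str, TaxonomyLabel],
    aligned: bool = False,
    drop_unlabeled: bool = True,
    max_unlabeled_fraction: float = 0.2,
) -> ReferenceDB:
    """Assemble a ReferenceDB from a FASTA file and a taxonomy table.

    Records without a taxonomy entry are dropped (when ``drop_unlabeled``)
    or kept with an empty label; if more than ``max_unlabeled_fraction`` of
    the FASTA lacks taxonomy the load is rejected with counts, since that
    usually signals mismatched inputs.
    """
    if not isinstance(taxonomy, Mapping):
        taxonomy = read_taxonomy(taxonomy)
    fasta = read_fasta(fasta_path)
    if not fasta:
        raise ValueError(f"no records in {fasta_path}")
    missing = [i for i, _ in fasta if i not in taxonomy]
    if len(missing) / len(fasta) > max_unlabeled_fraction:
        raise ValueError(
            f"{len(missing)}/{len(fasta)} FASTA records lack taxonomy "
            f"(first: {missing[0]!r}); check that the files belong together"
        )
    records = []
    for rec_id, seq in fasta:
        label = taxonomy.get(rec_id)
        if label is None:
            if drop_unlabeled:
                continue
            label = TaxonomyLabel()
        records.append(ReferenceRecord(rec_id, seq, label))
    return ReferenceDB(records, aligned=aligned)
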