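"""Criterion-based primer design over a synthetic aligned database.

Simulates a 2-clade reference alignment with one conserved 17-column
window planted at columns 101-117, scans for degenerate consensus primers
meeting the full criterion set (mismatches, clean ends, degeneracy cap,
length, no indels, no hairpins/self-dimers), and pairs the best forward
candidate with a reverse candidate.  The top hit should be exactly the
planted window with full target coverage and degeneracy 1 - the scan's
ground truth.
"""

from nestprime import DesignCriteria, degeneracy, pair_candidates, scan_candidates
from nestprime.synthetic import SimulationConfig, make_reference_db

db = make_reference_db(SimulationConfig(
    seed=4, n_clades=2, n_subclades_per_clade=2, n_records_per_subclade=3,
    gene_length=400,
    between_clade_divergence=0.25, between_subclade_divergence=0.10,
    within_subclade_divergence=0.05,
    conserved_windows=(
        (101, 117, "ACCAATGCCTGTTGAGA"),
        (301, 317, "TGCCAGACGCGTAACCA"),
    ),
))
criteria = DesignCriteria(max_degeneracy=4, length_min=17, length_max=17)

forwards = scan_candidates(db, ["clade1", "clade2"], criteria, "forward")
reverses = scan_candidates(db, ["clade1", "clade2"], criteria, "reverse")
print(f"{len(forwards)} forward / {len(reverses)} reverse admissible candidates")
top = forwards[0]
print(f"top forward: {top.oligo.sequence} at columns "
      f"{top.window_start}-{top.window_end}, coverage {top.coverage:.0%}, "
      f"degeneracy {degeneracy(top.oligo)}")

pairs = pair_candidates(forwards[:5], reverses[:5], criteria,
                        amplicon_min=150, amplicon_max=400)
best = pairs[0]
print(f"best pair: {best.forward.name} x {best.reverse.name}, "
      f"amplicon {best.amplicon_length} bp "
      f"({best.amplicon_start}-{best.amplicon_end}), Tm gap {best.tm_gap:.1f} C")
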