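"""Does the shorter nested amplicon still resolve the taxonomy?

Simulates a reference database with the published primer footprints planted
at their gene coordinates, truncates every record to the round-2 amplicon
region (as a real analysis truncates references to the sequenced region),
and summarizes within-clade pairwise identity and clade-pair resolvability.
A clade pair is resolvable when the most similar cross-clade sequence pair
is still less similar than the least similar within-clade pair - the
amplicon then cleanly separates the groups.
"""

from nestprime import group_similarity, resolvability, truncate_db_to_amplicon
from nestprime.design import make_pair
from nestprime.petb import PETB_F, PETB_R, PETB_50F
from nestprime.seqcore import ReferenceDB
from nestprime.synthetic import SimulationConfig, make_reference_db

db = make_reference_db(SimulationConfig(
    seed=11, n_clades=3, n_subclades_per_clade=2, n_records_per_subclade=3,
    gene_length=657,
    conserved_windows=(
        (22, 41, PETB_F.forward_footprint),
        (50, 66, "TCCAGGACATCGCTGAC"),
        (601, 618, PETB_R.forward_footprint),
    ),
))
db = ReferenceDB(db.records, aligned=False)

pair = make_pair(PETB_50F, PETB_R)
amplicons, dropped = truncate_db_to_amplicon(db, pair)
print(f"truncated {len(amplicons)} records to the round-2 region "
      f"({len(amplicons.records[0].sequence)} bp); dropped: {dropped or 'none'}")

for rep in group_similarity(amplicons, "clade"):
    print(f"  {rep.group}: within-identity min {rep.within_min:.1f}%, "
          f"mean {rep.within_mean:.1f}%  (n={rep.n_sequences})")

for v in resolvability(amplicons, "clade"):
    print(f"  {v.group_a} vs {v.group_b}: "
          f"{'resolvable' if v.resolvable else 'entangled'} "
          f"(between max {v.between_max:.1f}% < within min "
          f"{min(v.within_min_a, v.within_min_b):.1f}%)")
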