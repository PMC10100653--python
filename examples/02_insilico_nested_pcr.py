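"""In-silico standard and nested PCR on the benchmark template.

Builds the seeded 657-bp template that carries perfect binding sites for
all four published primers at their gene coordinates, then runs the
standard single-round protocol and the two-round nested protocol.  The
printed lengths (597 bp standard; 613 bp round 1, 569 bp round 2, primers
included) are the products the protocols are designed to yield; the insert
is what remains after primer trimming and is what gets sequenced.
"""

from nestprime import amplify, make_benchmark_template, nested_amplify, trim_primers
from nestprime.petb import PETB_F, PETB_R, PETB_50F, PETB_634R

template = make_benchmark_template()
print(f"template: {template.id}, {len(template)} bp")

(standard,) = amplify(template, PETB_F, PETB_R)
insert, ins_start, ins_end = trim_primers(standard)
print(f"standard PCR  : {standard.length} bp ({standard.start}-{standard.end}), "
      f"insert {len(insert)} bp ({ins_start}-{ins_end})")

(round2,) = nested_amplify(template, (PETB_F, PETB_634R), (PETB_50F, PETB_R))
print(f"nested round 1: {round2.parent.length} bp "
      f"({round2.parent.start}-{round2.parent.end})")
insert2, _, _ = trim_primers(round2)
print(f"nested round 2: {round2.length} bp ({round2.start}-{round2.end}), "
      f"insert {len(insert2)} bp")
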