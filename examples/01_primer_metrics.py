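"""Per-oligo metrics for the published petB primer sets.

Prints degeneracy (number of plain-sequence expansions), ambiguity-weighted
GC%, and the Wallace-rule melting-temperature estimate for the four primers
of the standard and nested petB protocols.  Degeneracy 12 and 8 for the two
new degenerate primers mean 12 and 8 distinct oligos in each synthesis mix;
the Tm range shows the spread across those variants.
"""

from nestprime import degeneracy, gc_percent, tm_estimate
from nestprime.petb import PETB_F, PETB_R, PETB_50F, PETB_634R

print(f"{'primer':<10} {'sequence':<22} {'deg':>4} {'GC%':>6} {'Tm mean':>8} {'Tm range':>12}")
for primer in (PETB_F, PETB_R, PETB_50F, PETB_634R):
    tm = tm_estimate(primer, "wallace")
    print(f"{primer.name:<10} {primer.sequence:<22} {degeneracy(primer):>4} "
          f"{gc_percent(primer):>6.1f} {tm.mean:>8.1f} "
          f"{f'{tm.min:.0f}-{tm.max:.0f}':>12}")
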