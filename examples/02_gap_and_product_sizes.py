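"""Gap and product-size arithmetic on the published transporter tables.

Each candidate pair's location string places its two members on a
reference protein; the gap is start3 - end5 (aa) and the expected
bridging-product size is the designed primer-bounded size plus 3 nt
per missing residue.
"""

from unibridge import datasets
from unibridge.pair_selection import parse_reference_location
from unibridge.primer_design import estimated_size

table = datasets.candidate_pairs("NRT")
print("pair  location            gap(aa)  designed(bp)  estimated(bp)")
for row in table.head(5).itertuples(index=False):
    loc = parse_reference_location(row.reference_location)
    est = estimated_size(int(row.designed_bp), loc.gap_aa)
    gap = "none" if loc.gap_aa is None else loc.gap_aa
    print(f"{row.number:>4}  {row.reference_location:<18}  {gap!s:>7}  "
          f"{row.designed_bp:>12}  {est:>13}")
print()
print(f"NRT validation success rate: {datasets.validation_success_rate('NRT'):.0f}%")
print(f"PHT validation success rate: {datasets.validation_success_rate('PHT'):.0f}%")
# A gapless ("none") pair needs no extra bases: estimated equals the
# designed size. The success rates are validated pairs / tested pairs.
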