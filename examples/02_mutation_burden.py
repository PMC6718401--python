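"""Expected mutation burden and exome detectability.

Cells accumulate ~25 substitutions per genome per division during normal
growth; ~1.5% land in exons.  Because bulk exome sequencing only sees a
mutation once its carriers make up >=10% of the dish (3 x 10^4 of 3 x 10^5
cells), the detectable burden is set by the clonal structure of the culture,
not by the raw mutation count.
"""

from msiburst import (
    detectable_cell_threshold,
    divisions_to_reach,
    estimate_detectable_ip28,
    expected_exonic_substitutions,
)

print("divisions from fertilization to growth arrest (P8): 48")
print(f"expected exonic substitutions detectable at IP1:    "
      f"{expected_exonic_substitutions(48):.0f}")
print(f"divisions for one immortalized cell to fill a dish: "
      f"{divisions_to_reach(300_000)}")
print(f"carrier-cell detectability threshold:               "
      f"{detectable_cell_threshold()}")

estimate = estimate_detectable_ip28(replicates=100, seed=0)
print(f"\nexpansion-phase mutations newly detectable at IP28: {estimate:.2f}")
print("\n(Monte-Carlo over the 19-division expansion tree, first 3 divisions")
print("excluded, carriers propagated through 27 Binomial(4n, 1/4) passages.)")
print("Only mutations from the earliest non-excluded expansion divisions keep")
print("enough carriers to stay above threshold -- a handful, which is why an")
print("observed burden far above this expectation indicates a hypermutation")
print("burst rather than canonical replication errors.")
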