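"""Score FACT-B item responses: reverse scoring, half-rule, composites.

Builds two respondents by hand — one fully answered, one with a partially
missing physical well-being subscale — and prints their subscale and
composite scores.
"""

import factbmap as fm

manifest = fm.default_manifest()

# respondent A answers everything at the best level (raw 0 on reverse-scored
# items, raw 4 otherwise)
best = {it.item_id: (0 if it.negatively_worded else 4) for it in manifest.items}

# respondent B answers like A but skips 4 of the 7 PWB items: only 3 remain,
# which is not "more than half", so PWB (and FACT-G/TOI/total) are undefined
partial = dict(best)
for item_id in manifest.item_ids("PWB")[:4]:
    del partial[item_id]

for name, responses in [("fully answered", best), ("3 of 7 PWB items", partial)]:
    prof = fm.score_form(responses, manifest)
    fact_g, toi, total = fm.compute_composites(prof)
    print(f"{name}:")
    print(f"  PWB={prof.pwb} SWB={prof.swb} EWB={prof.ewb} FWB={prof.fwb} BCS={prof.bcs}")
    print(f"  FACT-G={fact_g} TOI={toi} FACT-B total={total}")

# the half-rule in isolation: 4 of 7 items answered, each 2 -> prorated 14
print("prorated score [2,2,2,2,-,-,-]:", fm.score_subscale([2, 2, 2, 2, None, None, None]))
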