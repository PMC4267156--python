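"""EQ-5D-5L utilities from a value set, and the bounded-outcome transform.

Uses the synthetic stub value set (anchors of the Japanese crosswalk range:
full health = 1, floor = -0.111) and shows the logit transform that logistic
quantile regression applies to keep predictions inside the utility range.
"""

import factbmap as fm

vs = fm.japanese_stub()
for state in [(1, 1, 1, 1, 1), (2, 2, 1, 2, 1), (3, 2, 4, 3, 2), (5, 5, 5, 5, 5)]:
    print(f"state {state} -> utility {fm.utility_of(state, vs):+.4f}")
# 1 is full health; the floor matches the crosswalk range; middle states are
# synthetic-tariff interpolations, monotone in every dimension.

bounds = fm.bounds_preset("japanese")  # y_min = 0.17885, y_max = 1.001
print(f"\nbounds: ({bounds.y_min}, {bounds.y_max})")
h = fm.logit_transform(0.740, bounds)  # 0.740 = a typical median utility
print(f"h(0.740) = {h:.4f}")
print(f"inverse round trip: {fm.inverse_logit_transform(h, bounds):.4f}")

# bounds can also be derived from data: half the smallest utility increment
# below the smallest observed utility
derived = fm.derive_bounds(observed_min=0.179, smallest_increment=0.01)
print(f"derived bounds from min 0.179: ({derived.y_min:.4f}, {derived.y_max})")
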