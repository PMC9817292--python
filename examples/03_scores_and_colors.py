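"""Attach a per-atom score vector, normalize it and map scores to colors.

A 3-atom score vector on the 5-token string C1CC1 is spread onto the atom
tokens with 0.0 on the ring digits.  The default colormap domain is the
molecule's max |score|; overriding it to a smaller interval clamps stronger
scores to the endpoint color and full bar height.
"""

from smilight import (
    attach_scores,
    default_domain,
    normalize,
    score_to_color,
    threshold_cutoffs,
    tokenize,
)

scored = attach_scores(tokenize("C1CC1"), [0.1, 0.2, 0.6])
print("token scores:", scored.scores)

domain = default_domain(scored)
print("default domain:", domain)

override = (-0.33, 0.33)
print(f"normalize(0.6) in {override}: {normalize(0.6, override)}")
print("color at 0.6 (clamped to endpoint):",
      score_to_color(0.6, override, "red_blue"))
print("color at 0:", score_to_color(0.0, override, "red_blue"))

cutoffs = threshold_cutoffs([0.5], (-0.5, 0, 0.5))
print("threshold 0.5 under domain (-0.5, 0, 0.5) cuts at |score| >=",
      cutoffs[0])
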