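"""Why realistic prior variances for standardized log odds ratios are tiny.

delta_max(OR) bounds the standardized effect size attainable by any 2x2
design with a given odds ratio; its global maximum over all odds ratios is
the Laplace Limit constant.  Those bounds pin the variance of any credible
zero-centered prior on delta.
"""

from pintervals import (
    delta_max,
    global_delta_max,
    popoviciu_bound,
    prior_variance_from_or_tail,
)

for or_value in (1.2, 2.0, 4.0, 10.0):
    print(f"delta_max(OR={or_value:>4}) = {delta_max(or_value):.4f}")
# Even OR = 10 cannot move the standardized effect past ~0.49.

or_at_max, d_at_max = global_delta_max()
print(f"global maximum: OR = {or_at_max:.2f}, delta = {d_at_max:.6f}")
# -> OR = 121.35, delta = 0.662743 (the Laplace Limit constant): no odds
#    ratio, however extreme, yields |delta| beyond ~0.663.

s0_sq = prior_variance_from_or_tail(3.0, 0.01)
print(f"prior variance with Pr(OR >= 3) = 1%: s0^2 = {s0_sq:.4f}")
# -> ~0.013: if odds ratios above 3 occur 1% of the time, the prior sd of
#    delta is ~0.11 -- nothing like the flat prior implicit in P-intervals.

print(f"Popoviciu bound on s0^2 over the full delta range: "
      f"{popoviciu_bound(-d_at_max, d_at_max):.5f}")
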