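"""Inspect and adjust the relative importance of the nine criteria.

Prints the model's built-in importance percentages, then doubles down on
flare history (rating 100) while halving the parental-preference rating,
and shows how the withdrawal likelihood moves for a child with a flare
history.
"""

from biowean import (
    CRITERIA,
    CoefficientSet,
    CriterionProfile,
    derive_relative_importance,
    predict_with_adjustment,
    predict_withdrawal,
    to_percent,
)

coeffs = CoefficientSet.default()
weights = derive_relative_importance(coeffs)
rounded, _ = to_percent(weights)

print("built-in relative importance (rating 0-100 / percent):")
for name in sorted(CRITERIA, key=lambda n: -coeffs.betas[n]):
    print(f"  {name:<20} rating {weights.ratings[name]:5.1f}   {rounded[name]:3d}%")

profile = CriterionProfile(cid_months=12.0, flare_history=1)
before = predict_withdrawal(profile, coeffs)

ratings = dict(weights.ratings)
ratings["flare_history"] = 100.0
ratings["prefer_continue"] /= 2.0
after = predict_with_adjustment(profile, coeffs, ratings)

print(f"\nP(withdraw) default weights   {before.p_withdraw:.4f}")
print(f"P(withdraw) adjusted weights  {after.p_withdraw:.4f}")

# Raising a criterion's rating shifts coefficient mass onto it (total
# mass is conserved), so a present risk factor weighs more heavily
# against withdrawal and the likelihood drops.
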