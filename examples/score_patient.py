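"""Score one child's withdrawal likelihood.

A child with RF-positive JIA and a history of flares, whose parents
prefer to continue therapy, has been in clinically inactive disease for
15 months.  The script prints the full decomposition of the prediction.
"""

from biowean import CoefficientSet, CriterionProfile, predict_withdrawal

profile = CriterionProfile(
    cid_months=15.0,
    rf_positive=1,
    flare_history=1,
    prefer_continue=1,
)
coeffs = CoefficientSet.default()
pred = predict_withdrawal(profile, coeffs)

print(f"continuation utility      {pred.utility_continue:+.4f}")
print(f"P(continue | profile)     {pred.p_continue_given_profile:.4f}")
print(f"baseline withdrawal       {pred.baseline_clamped:.4f} (raw {pred.baseline_raw:.4f})")
print(f"P(withdraw)               {pred.p_withdraw:.4f}")

# The utility sums the published coefficients of the present risk
# factors; each one raises the value of continuing therapy and so lowers
# the likelihood (last line) that peers would withdraw the biologic at
# this point in remission.
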