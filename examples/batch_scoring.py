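"""Score a CSV batch of patient profiles.

Builds a three-patient CSV in memory (extra columns pass through as
notes), scores every row, and prints one line per patient.
"""

from biowean import CoefficientSet, read_batch, score_batch

CSV = """\
patient_id,cid_months,slow_response,rf_positive,flare_history,joint_damage,uveitis_history,spine_involvement,tmj_involvement,treatment_failure,prefer_continue,site
NL-001,6,0,0,0,0,0,0,0,0,0,Utrecht
NL-002,12,1,0,1,0,1,0,0,0,1,Utrecht
CA-001,24,0,1,0,1,0,0,1,1,0,Toronto
"""

coeffs = CoefficientSet.default()
profiles = read_batch(CSV)
for report in score_batch(profiles, coeffs):
    pred = report.prediction
    flag = " (baseline clamped)" if pred.clamped else ""
    print(
        f"{report.patient_id}: P(withdraw) = {pred.p_withdraw:.3f} "
        f"[{report.inputs['cid_months']:.0f} mo CID]{flag}"
    )

# Each row's likelihood reflects its CID time (longer remission -> higher
# baseline) and its risk factors (each one lowers the likelihood peers
# would withdraw the biologic).
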