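"""Score the two behavioral instruments.

Simulates one sudden-motion DVC session and scores it under both DMD
conventions — the published formula counts false presses on noise in
the numerator; the corrected variant counts correct rejections — then
scores a complete six-location driving assessment.
"""

from leukodrive import (
    DSP_CATEGORIES,
    DspAssessment,
    dmd_ratio,
    score_dsp,
    simulate_dvc_session,
)

session = simulate_dvc_session(n_signal=40, n_noise=10, hit_rate=0.9,
                               false_alarm_rate=0.2, seed=5)
n_sig, n_noi, hits, fas = session.counts("sudden")
print(f"sudden-motion task: {hits}/{n_sig} hits, {fas}/{n_noi} false alarms")
for convention in ("verbatim", "corrected"):
    ratio = dmd_ratio(session, "sudden", convention)
    print(f"  DMD ratio ({convention:9s}) = {ratio:.2f} "
          f"({100 * ratio:.0f} on the cohort 0-100 scale)")

ratings = {loc: {cat: 3 for cat in cats}
           for loc, cats in DSP_CATEGORIES.items()}
ratings["P2"]["searching"] = 2  # one 'normal' rating at the right turn
scores = score_dsp(DspAssessment(ratings))
print(f"\nDSP per location: {scores.per_location}")
print(f"DSP total = {scores.total} (legal range 17-51; the reference "
      f"cohort mean is 38.3)")
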