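"""Reproduce the reference cohort's statistics from its printed tables.

Runs the whole statistical stage on the packaged summary tables (17
variables, n = 101): the correlation matrix with significance stars,
the six DSP and two DVC standardized-regression batteries, and the
maximum-likelihood path model

    DVC sudden <- age + brain atrophy + occipital LA
    DSP P2     <- DVC sudden        (exogenous variables free to covary)

whose df = 3 fit indices are the study's headline result.
"""

from leukodrive import run_analyses

report = run_analyses()

fit = report.path_fit.fit
print(f"path model: chi2(df={fit.df}) = {fit.chi2:.2f}, p = {fit.p:.3f}, "
      f"GFI = {fit.gfi:.3f}, AGFI = {fit.agfi:.3f}, RMSEA = {fit.rmsea:.3f}")
print("standardized paths:")
for row in report.path_fit.estimates.itertuples():
    print(f"  {row.outcome} <- {row.predictor:14s} {row.std:+.2f}")

p2 = report.dsp_regressions["dsp_p2"]
print(f"\nP2 (right turn) regression: R2 = {p2.r2:.2f}, "
      f"F({p2.df1},{p2.df2}) = {p2.f:.2f}")
print(f"  beta[DVC sudden]  = {p2.beta['dvc_sudden']:+.2f}")
print(f"  beta[parietal LA] = {p2.beta['la_parietal']:+.2f}")

dvc = report.dvc_regressions["dvc_sudden"]
print(f"\nDVC sudden regression: R2 = {dvc.r2:.2f}")
print(f"  beta[occipital LA]  = {dvc.beta['la_occipital']:+.2f}")
print(f"  beta[brain atrophy] = {dvc.beta['brain_atrophy']:+.2f}")
print("\nA non-significant chi2 with GFI/AGFI > 0.90 and RMSEA < 0.05 "
      "indicates a good fit.")
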