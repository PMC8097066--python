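"""Compare the Markov chain with the two-step first-order scheme.

The chain's intact-chain class is calibrated to decay exactly as
exp(-k1 t); the deterministic scheme C -> G -> HMF then shares that k1,
and its k2 is fitted to the chain's glucose class.  RMSE and CV quantify
how well the one-step scheme tracks the multi-generation scission cascade
— the residual mismatch is structural (glucose appears only after several
cleavage generations), which is precisely what the comparison exposes.
"""

from cellhydro import calibrated_agreement

for dist in ("gauss", "weibull"):
    res = calibrated_agreement(distribution=dist)
    print(f"\n{dist.capitalize()} scission, N = 100, k1 = {res.k1} 1/s:")
    print(f"  alpha scale factor  : {res.alpha_scale:.4f}")
    print(f"  fitted k2           : {res.k2_fitted:.3e} 1/s")
    print(f"  glucose RMSE        : {res.report.rmse['G']:.2f} g/L")
    print(f"  HMF RMSE            : {res.report.rmse['HMF']:.2f} g/L")
    peak = max(res.peak_cG, res.peak_cG_stochastic)
    print(f"  glucose peak        : {peak:.2f} g/L "
          f"(RMSE = {100 * res.report.rmse['G'] / peak:.0f}% of peak)")
print(
    "\nThe glucose error of ~15-35% of peak reflects the cascade lag: a"
    "\nchain must cleave many times before any fragment becomes glucose,"
    "\nwhile the first-order scheme produces glucose from the first instant."
)
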