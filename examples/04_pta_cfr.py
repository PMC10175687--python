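"""PTA and CFR of the recommended regimens against MRSA.

For each renal-function stratum's recommended regimen, simulates daily
exposure, computes the probability of attaining AUC/MIC >= 610 across the
MIC grid, and weights the PTAs by an MRSA MIC histogram to get the CFR.
"""

import numpy as np

from teicopk import cfr, final_model, pta_profile, recommend_regimen, simulate_regimen
from teicopk.pkpd import default_mic_distribution

model = final_model()
dist = default_mic_distribution()
print(f"MIC distribution ({dist.source}):")
print("  " + "  ".join(f"{m}:{p:.0%}" for m, p in zip(dist.mics, dist.fractions)))

rng = np.random.default_rng(11)
for gfr in (120.0, 90.0, 45.0, 15.0):
    spec = recommend_regimen(gfr)
    met = simulate_regimen(model, gfr, spec, 1000, rng)
    profile = pta_profile(met.auc_24h)
    c = cfr(profile, dist)
    print(f"GFR {gfr:5.0f}: PTA@0.5 {profile[0.5]:.2f}  PTA@1 {profile[1.0]:.2f}  "
          f"CFR {c:.2f}  ({spec.label})")

print("-> PTA is high at MIC 0.5 mg/L but no regimen reaches 90% at MIC 1; "
      "with the stratum-adjusted (interval-stretched) maintenance doses the "
      "CFR stays in the 0.7-0.85 range - empirical teicoplanin cover of MRSA "
      "is moderate at best.")
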