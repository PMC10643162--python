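"""Fit polymerization and P_i-release rates from bulk fluorescence traces.

Generates three noisy replicate timecourses of a seeded polymerization
assay (pyrene channel) with delayed phosphate release (MDCC channel),
normalizes them, fits the mono-exponential polymerization rate and then
the single free release rate of the three-state kinetic scheme.
"""

import numpy as np

from backdoorflux.bulk_kinetics import (
    NormalizedTrace, fit_k_release, fit_kpoly, normalize_trace,
)
from backdoorflux.synthetic_data import BulkSimConfig, gen_bulk_traces

cfg = BulkSimConfig(k_poly=0.04, k_release=0.0065, noise_sd=0.01,
                    n_replicates=3, seed=1)
traces = gen_bulk_traces(cfg)

k_poly, k_poly_se = fit_kpoly([normalize_trace(t, "pyrene") for t in traces])
mdcc = [normalize_trace(t, "mdcc") for t in traces]
avg = NormalizedTrace(time=mdcc[0].time,
                      value=np.mean([m.value for m in mdcc], axis=0))
fit = fit_k_release(avg, k_poly=k_poly)

print(f"k_poly     = {k_poly:.4f} +/- {k_poly_se:.4f} 1/s  (planted 0.04)")
print(f"k_release  = {fit.k_release:.5f} 1/s            (planted 0.0065)")
print(f"half-time  = {fit.half_time:.0f} s")
print("The release channel lags polymerization by the half-time ln2/k;"
      " a fit within a few percent of the planted rates shows the"
      " two-channel analysis resolves that delay.")
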