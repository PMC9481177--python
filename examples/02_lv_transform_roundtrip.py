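"""Invert a simulated recording back into its latent growth parameters.

A positive network timeseries is generated by the explicit-Euler forward
model with a known, time-varying alpha trajectory; the Lotka-Volterra
Transform then recovers those alphas exactly from the series and the
connectivity matrix alone.  This noiseless round trip is the transform's
defining contract.
"""

import numpy as np

import lvscape as lv
from lvscape.transform import TimeSeries, reconstruct_step

rng = np.random.default_rng(0)
sc = lv.generate_sc(7, density=0.5, seed=123)
h = lv.h_for_tr(2000.0)  # discretisation step at TR = 2000 ms

alphas_true = rng.normal(0.2, 0.35, size=(99, 7))
u = rng.uniform(0.2, 1.0, size=7)
rows = [u]
for t in range(99):
    u = reconstruct_step(u, alphas_true[t], sc, h, g=0.27)
    rows.append(u)

series = TimeSeries(values=np.array(rows), tr_ms=2000.0)
recovered = lv.lvt_transform(series, sc, g=0.27)

err = np.abs(recovered.alphas - alphas_true).max()
print(f"timepoints        : {series.n_timepoints}")
print(f"step h            : {h:.3e}  (3.55e-4 at TR 2000 ms, proportional to TR)")
print(f"max |alpha error| : {err:.3e}")
print()
print("The recovered trajectory reproduces every observed increment exactly,")
print("so downstream landscape measures see the same dynamics that generated")
print("the data.")
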