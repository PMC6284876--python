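"""Compute an apparent-diffusion-coefficient map from a b=0/b=1000 pair.

Simulates diffusion-weighted signal decay S_b = S_0 * exp(-b * ADC) for a
two-compartment phantom (free-water-like rim around a restricted core) and
recovers the ADC map voxelwise; the printed means should match the ground
truth used to simulate the decay.
"""

import numpy as np

from radtex import ADCInputs, compute_adc

truth = np.full((32, 32), 2.5e-3)  # mm^2/s, free-water-like
truth[8:24, 8:24] = 0.7e-3         # restricted diffusion in the core

rng = np.random.default_rng(0)
s0 = rng.normal(1000.0, 5.0, truth.shape).clip(min=0)
sb = s0 * np.exp(-1000.0 * truth)

adc = compute_adc(ADCInputs(s0=s0, sb=sb, b1=1000.0))

core = adc[8:24, 8:24].mean()
rim = np.mean(adc[truth == 2.5e-3])
print(f"recovered core ADC: {core:.3e} mm^2/s (truth 7.0e-04)")
print(f"recovered rim  ADC: {rim:.3e} mm^2/s (truth 2.5e-03)")
print("voxelwise ln(S0/Sb)/b recovers the planted diffusion contrast.")
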