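"""Simulate one voxel: population AIF -> extended Tofts -> SPGR signal.

Builds the default 60-frame, 5-s acquisition, evaluates the population
arterial input function, generates a tumor-like tissue curve and converts it
to signal intensity and back.
"""
import numpy as np

from dcepk import (
    AcquisitionParams,
    PKParams,
    TimeGrid,
    concentration_to_signal,
    population_aif,
    signal_to_concentration,
    tofts_forward,
)

grid = TimeGrid.uniform()  # 60 frames, dt = 5 s, 5 baseline frames
aif = population_aif(grid)
print(f"AIF peak: {aif.cp.max():.2f} mM at t = {grid.times[aif.cp.argmax()]*60:.0f} s")

params = PKParams(ktrans=0.15, ve=0.35, vp=0.06)  # enhancing tumor rim
ct = tofts_forward(params, aif)
print(f"tissue concentration peak: {ct.max():.3f} mM; final frame {ct[-1]:.3f} mM")

acq = AcquisitionParams()
signal = concentration_to_signal(ct, acq)
print(f"signal enhancement: baseline {signal[0]:.1f} -> peak {signal.max():.1f} (a.u.)")

recovered, invalid = signal_to_concentration(signal, acq, grid.n_baseline)
print(f"round-trip max error: {np.abs(recovered - ct).max():.2e} mM "
      f"({int(invalid.sum())} non-invertible frames)")
# The round-trip error is at machine precision: the SPGR model is inverted
# exactly on noiseless data.
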