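"""Synthetic noisy recordings and P/4 leak subtraction.

Corrupts a clean model sweep with Gaussian noise, linear leak and a
capacitive step transient, applies P/4 subtraction (four 1/4-scaled
channel-free pulses), and shows that the corrected trace recovers the clean
current.  This is how the analysis pipeline is validated without any
experimental data.
"""

import numpy as np

from tetranav import (NoiseModel, VoltageProtocol, corrupt, integrate,
                      load_parameter_table, p_over_n_subtract)

params = load_parameter_table("CF", 7.4)
proto = VoltageProtocol(((-20.0, 20.0),), holding=-150.0)
clean = integrate(params, proto, rtol=1e-6, atol=1e-8)

peak = float(np.max(np.abs(clean.i_ionic)))
noise = NoiseModel(sd=0.01 * peak, g_leak=0.02, cap_scale=0.3, cap_tau=0.15,
                   seed=42)
sweep = corrupt(clean, noise)
corrected = p_over_n_subtract(sweep, n=4)

rms_raw = float(np.sqrt(np.mean((sweep.i_raw - clean.i_ionic) ** 2)))
rms_corr = float(np.sqrt(np.mean((corrected - clean.i_ionic) ** 2)))
print(f"peak inward current:                {clean.i_ionic.min():.2f}")
print(f"RMS artifact before subtraction:    {rms_raw:.3f}")
print(f"RMS residual after P/4 subtraction: {rms_corr:.3f}")
print(f"expected residual (sqrt(1+4) * sd): {np.sqrt(5) * noise.sd:.3f}")
print("\nP/4 removes the deterministic leak and capacitive components")
print("exactly; what remains is the predicted noise floor.")
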