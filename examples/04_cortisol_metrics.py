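"""Salivary cortisol curve metrics: AUCs, maximum increase, S1-S4 slope."""

import numpy as np

from coldface import (CortisolProfile, SimulationConfig, auc_g, auc_i,
                      build_mist_protocol, response_metrics,
                      simulate_cortisol_profile)

protocol = build_mist_protocol()
# noiseless profiles make the structural condition difference visible
cfg = SimulationConfig(seed=9)
cfg.cortisol.amplitude_sd_pct = 0.0
cfg.cortisol.noise_sd = 0.0

for i, condition in enumerate(("Control", "CFT")):
    prof, truth = simulate_cortisol_profile(
        cfg, condition, protocol, np.random.default_rng([9, i]))
    m = response_metrics(prof)
    print(f"{condition:7s}: c = {np.round(prof.conc_nmol_l, 1)} nmol/L")
    print(f"         AUC_G {m.auc_g:6.1f}  AUC_I {m.auc_i:6.1f} nmol*min/L   "
          f"dc_max {m.delta_c_max:6.1f} %   a_S1S4 {m.slope_s1_s4:.3f} nmol/(L*min)")

# AUC_G measures total cortisol output over S1..S6; AUC_I subtracts the
# baseline rectangle and indexes reactivity (negative when the curve decays
# below its first sample). The blunted CFT response shows a much smaller
# maximum increase over baseline than the Control response.
flat = CortisolProfile("flat", np.array([0, 30, 40, 50, 60, 70.0]),
                       np.full(6, 5.0))
print(f"\nsanity: constant 5 nmol/L profile -> AUC_G {auc_g(flat):.0f} "
      f"(= 5 x 70), AUC_I {auc_i(flat):.0f}")
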