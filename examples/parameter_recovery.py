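"""Recovering rate coefficients from synthetic relaxation trajectories.

Simulates a two-compartment oxygen-transfer experiment with a known
transfer coefficient, then re-estimates the coefficient from the observed
trajectory by least squares — noiseless and with 1% multiplicative noise.
"""

import numpy as np

from tcatsim.calibrate import fit_transfer_coefficient
from tcatsim.fixtures import build_twobox_transfer_fixture
from tcatsim.model2p import simulate

K_TRUE = 1.5e-11
cfg = build_twobox_transfer_fixture(k_transfer=K_TRUE, perturbation=2.0,
                                    t_end=5e3, n_out=101)
obs = simulate(cfg).omega_f["o"].mean(axis=1)
print(f"synthetic trajectory: omega_o(fluid) {obs[0]:.4e} -> {obs[-1]:.4e}")

est = fit_transfer_coefficient(cfg, obs, "o", initial_guess=3 * K_TRUE)
print(f"noiseless recovery: true {K_TRUE:.3e}, estimated {est:.3e} "
      f"({100 * abs(est - K_TRUE) / K_TRUE:.2e} % error)")

rng = np.random.default_rng(1000)
noisy = obs * (1.0 + 0.01 * rng.standard_normal(obs.size))
est_n = fit_transfer_coefficient(cfg, noisy, "o", initial_guess=2 * K_TRUE)
print(f"1% noise recovery:  estimated {est_n:.3e} "
      f"({100 * abs(est_n - K_TRUE) / K_TRUE:.2f} % error)")
# The relaxation rate constant is proportional to the transfer coefficient,
# so an informative trajectory (large initial disequilibrium, sampling
# within a few relaxation times) pins the coefficient down to percent level
# even under measurement noise.
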