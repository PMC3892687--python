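"""Declared study conditions for the bundled case studies.

All values in this file are synthetic defaults chosen once to emulate a
typical oral-absorption pharmacokinetic experiment and a yeast batch-culture
glutamine-depletion experiment; they are this package's own reconstruction of
plausible conditions, not measured values.  Everything the generators and
default boxes use lives here so that a run is fully specified by (case, seed).
"""

import numpy as np

# --------------------------------------------------------------------------
# Pharmacokinetic case: drug amount Q [mg] in the gastrointestinal tract,
# concentration C [mg/l] in blood plasma; time in hours.  Only C is observed.
# --------------------------------------------------------------------------

PK_THETA_TRUE = {
    "V_max": 10.0,   # mg/h, maximal transport rate gut -> plasma
    "K_m": 3.0,      # mg, amount of Q at half-maximal transport (deeply
                     # saturated at the dose below, so mass-action uptake is
                     # a genuinely wrong approximation)
    "C_L": 5.0,      # l/h, plasma clearance
    "V": 15.0,       # l, plasma volume
}
PK_Q0 = 50.0         # mg, oral dose
PK_C0 = 0.0          # mg/l
PK_T0 = 0.0
# 20 equally spaced sampling times across the absorption-clearance window
PK_TIMES = np.linspace(0.5, 10.0, 20)
PK_RHO = 0.1         # proportional measurement error coefficient
PK_Y_FLOOR = 0.01    # mg/l, output floor for measurement-SD evaluation

# broad exploration box: eight orders of magnitude for every unknown (log10)
PK_WIDE = (-4.0, 4.0)

# comparison priors: uniform log10 boxes, two decades around plausible values.
# These are part of the declared model-comparison configuration.
PK_PRIOR_BOX = {
    "k_A": (-1.5, 0.5),
    "V_max": (0.0, 2.0),
    "K_m": (0.0, 2.0),
    "C_L": (-0.3, 1.7),
    "V": (0.2, 2.2),
    "sigma_Q": (-3.0, 1.0),
    "sigma_C": (-3.0, 0.5),
    "k_A0": (-2.5, 0.5),
    "sigma_k_A": (-3.0, 0.5),
}

# --------------------------------------------------------------------------
# Glutamine transport case: extracellular Q [mM], intracellular C [mM],
# time in minutes with the metabolic shift (glutamine depletion) at t = 0.
# Both Q and C are observed.
# --------------------------------------------------------------------------

GLN_THETA_TRUE = {
    "V_max": 0.75,   # mM/min, constitutive (millimolar) uptake capacity
    "K_m": 14.0,     # mM, constitutive-uptake affinity
    "V_2": 0.8,      # mM/min, regulated-uptake capacity
    "K_2": 1.0,      # mM, regulated-uptake affinity
    "D": 0.10,       # 1/min, intracellular degradation/consumption rate
    "k_w": 0.04,     # 1/min, activation rate of the regulated permease pool
                     # (a ~40-min derepression ramp)
    "K": 4.0,        # mM, external-glutamine threshold triggering activation
}
GLN_T0 = -60.0       # min, culture start relative to the shift
GLN_Q0 = 14.0        # mM extracellular glutamine at t0; with the growth input
                     # below, external glutamine crosses the activation
                     # threshold K just after t = 0 — the metabolic shift
GLN_C0 = 3.75        # mM intracellular glutamine at t0 (pre-shift steady state)
GLN_W0 = 0.0         # regulated permease pool starts inactive

# cell-count input: phi(t) = U(t) Vc / Vf, the cell-to-medium volume ratio of
# a logistically growing culture (dimensionless); the scale is calibrated so
# glutamine depletion (the shift) lands at t = 0
GLN_PHI_MAX = 1.1284
GLN_PHI_RATE = 0.03      # 1/min
GLN_PHI_TMID = -30.0     # min
GLN_GATE_WIDTH = 0.05    # mM, width of the smoothed activation gate

# sampling schedules straddling the shift: extracellular on a uniform grid,
# intracellular concentrated in the post-shift response window
GLN_TIMES_EXTRA = np.arange(-60.0, 161.0, 10.0)         # 23 extracellular points
GLN_TIMES_INTRA = np.array([-40.0, -30.0, -20.0, -10.0, 0.0, 8.0, 16.0, 24.0,
                            32.0, 40.0, 48.0, 56.0, 70.0, 85.0])  # 14 points
GLN_RHO = 0.05
GLN_Y_FLOOR = 2.0    # mM: measurement SD floored at rho * this quantification
                     # scale (0.1 mM), the assay's effective detection limit

# e1rMM / e2rMM extension defaults (truth values unused by the generator;
# listed for box construction only)
GLN_PRIOR_BOX = {
    "V_max": (-1.5, 0.5),
    "K_m": (-0.5, 1.5),    # permease affinities above ~30 mM are implausible
    "V_2": (-1.5, 0.5),
    "K_2": (-1.5, 1.0),
    "D": (-2.0, 0.0),
    "k_w": (-2.5, -0.5),
    "K": (0.0, 1.0),
    "V_3": (-2.5, 0.0),
    "K_3": (-0.5, 1.5),
    "V_4": (-2.5, 0.0),
    "K_4": (-3.5, -1.5),   # micromolar-range affinity
    "sigma_Q": (-3.0, 0.5),
    "sigma_C": (-3.0, 0.5),
    "sigma_W": (-3.0, 0.0),
}
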