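# Default configuration: the standard parameter set of the seasonal
# host-parasite model.  The latency period tau is the main environmental
# axis (the analyses vary it between 1 and 3.5); 3 is the long-latency
# reference scenario.
alpha: 1.0e-6   # transmission rate, per parasite per time
beta: 400       # parasites released per host death
delta: 2.0      # free-parasite decay rate
mu_s: 0.2       # juvenile host death rate
mu_a: 0.015     # adult host death rate
l: 1.0          # maturation rate
tau: 3.0        # parasite latency period
gamma: 0.9      # parasite between-season survival probability
epsilon: 0.85   # host between-season survival probability
sigma: 600      # host fecundity (offspring per adult)
rho: 1.0e-4     # density-dependence strength
T: 4.0          # season length

t0: 0.0         # emergence start (value when held fixed)
tl: 0.5         # emergence period length (value when held fixed)

s_hat_1: 1.0e4  # season-1 host cohort
v_hat_1: 1.0e4  # season-1 parasite density

n_seasons: 150
resident_seasons: 300
evolve_trait: t0
evolve_step: 0.01
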