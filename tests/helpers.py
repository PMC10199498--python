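"""Independent oracles used by the test suite.

The Euler integrator here is deliberately primitive and shares no code with
the package's RK4 method-of-steps kernel: a fixed-step explicit Euler scheme
whose delayed term is read straight from the stored history by index offset.
It is the brute-force reference the solver is checked against.
"""

from __future__ import annotations

import numpy as np


def euler_season(
    s_hat: float,
    v_hat: float,
    t0: float,
    tl: float,
    params,
    h: float = 1e-4,
    sm_hat: float = 0.0,
    t0m: float = 0.0,
    tlm: float = 1.0,
):
    """Explicit-Euler integration of one season; returns (s_T, a_T, v_T, C_T,
    sm_T, am_T)."""
    n = int(round(params.T / h))
    lag = int(round(params.tau / h))
    s = np.zeros(n + 1)
    a = np.zeros(n + 1)
    v = np.zeros(n + 1)
    sm = np.zeros(n + 1)
    am = np.zeros(n + 1)
    c = 0.0
    v[0] = v_hat
    burst = params.alpha * params.beta * np.exp(-params.mu_s * params.tau)
    loss = params.mu_s + params.l
    for i in range(n):
        t = i * h
        g = (1.0 / tl) if (t0 <= t < t0 + tl) else 0.0
        gm = (1.0 / tlm) if (sm_hat > 0 and t0m <= t < t0m + tlm) else 0.0
        delayed = ((s[i - lag] + sm[i - lag]) * v[i - lag]
                   if i >= lag else 0.0)
        s[i + 1] = s[i] + h * (s_hat * g - loss * s[i]
                               - params.alpha * s[i] * v[i])
        a[i + 1] = a[i] + h * (params.l * s[i] - params.mu_a * a[i])
        sm[i + 1] = sm[i] + h * (sm_hat * gm - loss * sm[i]
                                 - params.alpha * sm[i] * v[i])
        am[i + 1] = am[i] + h * (params.l * sm[i] - params.mu_a * am[i])
        v[i + 1] = v[i] + h * (burst * delayed - params.delta * v[i])
        c += h * params.alpha * s[i] * v[i]
    return s[-1], a[-1], v[-1], c, sm[-1], am[-1]


def phi_quadrature(traits, params) -> float:
    """Maturation probability by numerical quadrature of the survival
    integral (independent of the package's closed form)."""
    from scipy.integrate import quad

    l, mu_s, mu_a, T = params.l, params.mu_s, params.mu_a, params.T
    k = mu_s + l - mu_a

    def P(e: float) -> float:
        w = T - e
        if abs(k) < 1e-12:
            return l * w * np.exp(-mu_a * w)
        return l * np.exp(-mu_a * w) * (1.0 - np.exp(-k * w)) / k

    e2 = min(traits.t0 + traits.tl, T)
    if e2 <= traits.t0:
        return 0.0
    value, _ = quad(P, traits.t0, e2, epsabs=1e-12, epsrel=1e-12)
    return value / traits.tl
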