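"""Low-level within-season integration kernel.

One season of the delay differential system is integrated by the method of
steps on a fixed grid that contains every non-smooth point of the vector
field: the edges of the (resident and mutant) emergence pulses, the delay
onset ``tau``, and all of their forward images under shifts by ``tau``
(discontinuities in a DDE propagate through the delay as progressively
milder kinks).  Between consecutive grid nodes the right-hand side is smooth,
so a classical RK4 step is taken per grid interval; the delayed infection
term is read back from the already-computed dense history by linear
interpolation (the delay ``tau`` always exceeds the step, so the lookup never
runs ahead of the front).

State layout per node: s, a, v, C, s_m, a_m, C_m where C is the cumulative
number of infection events ``integral alpha*s*v dt`` (used for prevalence)
and the ``_m`` columns are the rare-mutant analogues (identically zero when
no mutant is present).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_grid", "integrate_season_kernel"]

#: Default number of RK4 steps per unit time.
STEPS_PER_UNIT = 2000


def build_grid(
    T: float,
    tau: float,
    pulse_edges: tuple[float, ...],
    steps_per_unit: int = STEPS_PER_UNIT,
) -> np.ndarray:
    """Return the season time grid: uniform mesh refined by all breakpoints.

    ``pulse_edges`` are the emergence-window edges (t0, t0+tl, and the mutant
    pair when present).  Breakpoints are those edges, the delay onset, and
    every forward shift by multiples of ``tau`` that lands inside the season.
    """
    if tau <= 4.0 / steps_per_unit:
        raise ValueError(
            f"latency period tau={tau} is too short for the grid resolution "
            f"({steps_per_unit} steps per unit time); increase steps_per_unit"
        )
    breaks = {0.0, T}
    seeds = set(pulse_edges) | {0.0}
    for b in seeds:
        k = 0
        while True:
            x = b + k * tau
            if x >= T:
                break
            if x > 0.0:
                breaks.add(x)
            k += 1
    n_uniform = max(8, int(round(T * steps_per_unit)))
    grid = np.union1d(
        np.linspace(0.0, T, n_uniform + 1), np.array(sorted(breaks))
    )
    # drop near-duplicate nodes so RK4 never takes a zero-length step
    keep = np.empty(grid.size, dtype=np.bool_)
    keep[0] = True
    keep[1:] = np.diff(grid) > 1e-13
    return np.ascontiguousarray(grid[keep])


@njit(cache=True)
def _interp_history(tg, ys, yv, ysm, i_front, td):
    """Linear interpolation of (s + s_m) * v at delayed time ``td``.

    Only nodes with index <= i_front are populated.  Negative ``td`` means
    the delayed time falls before the season start, where there are no
    juveniles and hence no delayed infections.
    """
    if td < 0.0:
        return 0.0
    if td <= tg[0]:
        return (ys[0] + ysm[0]) * yv[0]
    j = np.searchsorted(tg[: i_front + 1], td)
    if j > i_front:
        j = i_front
    t1 = tg[j - 1]
    t2 = tg[j]
    w = (td - t1) / (t2 - t1)
    s_d = ys[j - 1] + w * (ys[j] - ys[j - 1])
    sm_d = ysm[j - 1] + w * (ysm[j] - ysm[j - 1])
    v_d = yv[j - 1] + w * (yv[j] - yv[j - 1])
    return (s_d + sm_d) * v_d


@njit(cache=True)
def integrate_season_kernel(
    tg,
    v0,
    s_hat,
    t0,
    tl,
    sm_hat,
    t0m,
    tlm,
    alpha,
    beta,
    delta,
    mu_s,
    mu_a,
    l,
    tau,
    out,
):
    """Integrate one season on grid ``tg`` into ``out`` (n_nodes x 7).

    Columns of ``out``: s, a, v, C, s_m, a_m, C_m.  Initial juvenile and
    adult densities are zero (each season starts with an unemerged cohort);
    ``v0`` is the carried-over parasite density.  Parasite loss to
    transmission is neglected, so v only decays at rate ``delta`` and gains
    from completed infections delayed by ``tau`` and discounted by juvenile
    survival ``exp(-mu_s * tau)``.
    """
    n = tg.shape[0]
    out[:] = 0.0
    out[0, 2] = v0
    worst_neg = 0.0
    burst = alpha * beta * np.exp(-mu_s * tau)
    ys = out[:, 0]
    yv = out[:, 2]
    ysm = out[:, 4]

    for i in range(n - 1):
        ta = tg[i]
        tb = tg[i + 1]
        h = tb - ta
        tmid = 0.5 * (ta + tb)
        # the grid contains every pulse edge, so g is constant on (ta, tb)
        g = 1.0 / tl if (t0 <= tmid <= t0 + tl) else 0.0
        gm = 1.0 / tlm if (tlm > 0.0 and t0m <= tmid <= t0m + tlm) else 0.0
        em_s = s_hat * g
        em_m = sm_hat * gm
        # delayed infection forcing at the three RK4 stage times
        pa = burst * _interp_history(tg, ys, yv, ysm, i, ta - tau)
        pm = burst * _interp_history(tg, ys, yv, ysm, i, tmid - tau)
        pb = burst * _interp_history(tg, ys, yv, ysm, i, tb - tau)

        s = out[i, 0]
        a = out[i, 1]
        v = out[i, 2]
        c = out[i, 3]
        sm = out[i, 4]
        am = out[i, 5]
        cm = out[i, 6]

        # stage 1
        k1s = em_s - (mu_s + l) * s - alpha * s * v
        k1a = l * s - mu_a * a
        k1v = pa - delta * v
        k1c = alpha * s * v
        k1sm = em_m - (mu_s + l) * sm - alpha * sm * v
        k1am = l * sm - mu_a * am
        k1cm = alpha * sm * v
        # stage 2
        s2 = s + 0.5 * h * k1s
        a2 = a + 0.5 * h * k1a
        v2 = v + 0.5 * h * k1v
        sm2 = sm + 0.5 * h * k1sm
        am2 = am + 0.5 * h * k1am
        k2s = em_s - (mu_s + l) * s2 - alpha * s2 * v2
        k2a = l * s2 - mu_a * a2
        k2v = pm - delta * v2
        k2c = alpha * s2 * v2
        k2sm = em_m - (mu_s + l) * sm2 - alpha * sm2 * v2
        k2am = l * sm2 - mu_a * am2
        k2cm = alpha * sm2 * v2
        # stage 3
        s3 = s + 0.5 * h * k2s
        a3 = a + 0.5 * h * k2a
        v3 = v + 0.5 * h * k2v
        sm3 = sm + 0.5 * h * k2sm
        am3 = am + 0.5 * h * k2am
        k3s = em_s - (mu_s + l) * s3 - alpha * s3 * v3
        k3a = l * s3 - mu_a * a3
        k3v = pm - delta * v3
        k3c = alpha * s3 * v3
        k3sm = em_m - (mu_s + l) * sm3 - alpha * sm3 * v3
        k3am = l * sm3 - mu_a * am3
        k3cm = alpha * sm3 * v3
        # stage 4
        s4 = s + h * k3s
        a4 = a + h * k3a
        v4 = v + h * k3v
        sm4 = sm + h * k3sm
        am4 = am + h * k3am
        k4s = em_s - (mu_s + l) * s4 - alpha * s4 * v4
        k4a = l * s4 - mu_a * a4
        k4v = pb - delta * v4
        k4c = alpha * s4 * v4
        k4sm = em_m - (mu_s + l) * sm4 - alpha * sm4 * v4
        k4am = l * sm4 - mu_a * am4
        k4cm = alpha * sm4 * v4

        w = h / 6.0
        s_new = s + w * (k1s + 2.0 * (k2s + k3s) + k4s)
        a_new = a + w * (k1a + 2.0 * (k2a + k3a) + k4a)
        v_new = v + w * (k1v + 2.0 * (k2v + k3v) + k4v)
        c_new = c + w * (k1c + 2.0 * (k2c + k3c) + k4c)
        sm_new = sm + w * (k1sm + 2.0 * (k2sm + k3sm) + k4sm)
        am_new = am + w * (k1am + 2.0 * (k2am + k3am) + k4am)
        cm_new = cm + w * (k1cm + 2.0 * (k2cm + k3cm) + k4cm)

        # densities cannot leave the nonnegative orthant; clip the tiny
        # negative excursions RK4 can produce at pulse edges, but report the
        # worst one so the caller can detect genuine step-size failures
        if s_new < worst_neg:
            worst_neg = s_new
        if a_new < worst_neg:
            worst_neg = a_new
        if v_new < worst_neg:
            worst_neg = v_new
        if sm_new < worst_neg:
            worst_neg = sm_new
        if am_new < worst_neg:
            worst_neg = am_new
        out[i + 1, 0] = s_new if s_new > 0.0 else 0.0
        out[i + 1, 1] = a_new if a_new > 0.0 else 0.0
        out[i + 1, 2] = v_new if v_new > 0.0 else 0.0
        out[i + 1, 3] = c_new if c_new > 0.0 else 0.0
        out[i + 1, 4] = sm_new if sm_new > 0.0 else 0.0
        out[i + 1, 5] = am_new if am_new > 0.0 else 0.0
        out[i + 1, 6] = cm_new if cm_new > 0.0 else 0.0
    return worst_neg
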