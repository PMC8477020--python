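"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's solver paths: fixed-step explicit
Euler for the fast subsystem, a day-by-day stiff solve of the complete
system for the slow engine, and brute-force definitional statistics.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import solve_ivp

from ptgtwin.core_model import MINUTES_PER_DAY, evaluate_rhs, steady_state


class _Raw:
    """Bare state container for RHS evaluation."""

    def __init__(self, q, a, s, c):
        self.q, self.a, self.s, self.c = q, a, s, c


def euler_fast(state0, ca_fn, phos_fn, cal_fn, params, duration,
               dt=0.01, sample_every=100):
    """Fixed-step Euler integration of the fast subsystem.

    Returns (times, states) with states sampled every ``sample_every``
    steps (plus the final state).
    """
    y = np.array([state0.q, state0.a, state0.s, state0.c], dtype=float)
    n = int(round(duration / dt))
    times, out = [0.0], [y.copy()]
    for i in range(n):
        t = i * dt
        d = evaluate_rhs(_Raw(*y), (ca_fn(t), phos_fn(t), cal_fn(t)),
                         params, mode="fast")
        y = y + dt * np.asarray(d)
        if (i + 1) % sample_every == 0 or i == n - 1:
            times.append((i + 1) * dt)
            out.append(y.copy())
    return np.asarray(times), np.asarray(out)


def full_system_daily(gland_mass0, daily_inputs, params,
                      rtol=1e-8, atol=1e-10):
    """Stiff integration of the complete system (fast + slow terms).

    Integrates minute-by-minute physiology over each day with the
    proliferation/apoptosis term active, returning plasma iPTH at the end
    of every day. Serves as the reference for the quasi-steady slow
    engine.
    """
    ca0, phos0, cal0 = daily_inputs[0]
    ss = steady_state(ca0, phos0, cal0, gland_mass0, params)
    y = np.array([ss.q, ss.a, ss.s, ss.c], dtype=float)
    c_daily = []
    for ca, phos, cal in daily_inputs:
        def rhs(t, yy):
            return evaluate_rhs(_Raw(*yy), (ca, phos, cal), params,
                                mode="slow")
        sol = solve_ivp(rhs, (0.0, MINUTES_PER_DAY), y, method="BDF",
                        rtol=rtol, atol=atol)
        y = sol.y[:, -1]
        c_daily.append(y[3])
    return np.asarray(c_daily)


def pearson_brute(x, y):
    """Product-moment correlation straight from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = float(np.sum((x - mx) * (y - my)))
    den = math.sqrt(float(np.sum((x - mx) ** 2)) *
                    float(np.sum((y - my) ** 2)))
    return num / den


def kendall_taub_brute(x, y):
    """Tau-b by exhaustive pair enumeration with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    den = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / den
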