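"""Independent oracles shared across test modules."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_creep_strain(ts: np.ndarray, E: float, eta: float, sigma0: float, a: float) -> np.ndarray:
    """Numerical initial-value solution of eta g' + E g = max(sigma0 - a t, 0).

    Integrated piecewise around the stress-clamp kink with tight
    tolerances; independent of the closed forms it checks.
    """
    ts = np.asarray(ts, dtype=float)
    t_clamp = sigma0 / a if a > 0 else np.inf

    def rhs(t, g):
        return [(max(sigma0 - a * t, 0.0) - E * g[0]) / eta]

    def segment(t0, t1, g0):
        return solve_ivp(
            rhs, (t0, t1), [g0], method="DOP853",
            rtol=1e-12, atol=1e-16, dense_output=True,
        )

    t_end = float(ts[-1])
    if t_clamp >= t_end:
        sol = segment(0.0, t_end, 0.0)
        return sol.sol(ts)[0]
    s1 = segment(0.0, t_clamp, 0.0)
    s2 = segment(t_clamp, t_end, float(s1.sol(t_clamp)[0]))
    return np.where(ts <= t_clamp, s1.sol(np.minimum(ts, t_clamp))[0],
                    s2.sol(np.maximum(ts, t_clamp))[0])


def ecdf_sup_distance(x, y) -> float:
    """Brute-force two-sample KS statistic by enumerating all jump points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pts = np.concatenate([x, y])
    fx = np.searchsorted(x, pts, side="right") / x.size
    fy = np.searchsorted(y, pts, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))
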