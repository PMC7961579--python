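"""Kelvin-Voigt creep analysis of optical-stretcher deformation curves.

The cell is modelled as a Kelvin-Voigt solid: a linear spring (Young's
modulus ``E``, Pa) in parallel with a linear dashpot (viscosity ``eta``,
Pa s), with relaxation time ``tau = eta / E``.  Under a step stress
``sigma0`` the creep response is

    gamma(t) = (sigma0 / E) * (1 - exp(-t / tau)).

The *active* extension adds a contractility parameter ``a`` (Pa/s): the
cell contracts against the optical stress, which is modelled as a linear
decrease of the effective step stress with time,

    eta * gamma'(t) + E * gamma(t) = max(sigma0 - a * t, 0),

with the effective stress clamped at zero once the contraction has fully
cancelled the optical load (contraction cannot reverse the sign of the
applied stress in this linear model).  On the unclamped range the closed
form is

    gamma(t) = (sigma0/E)(1 - e^{-t/tau}) - (a/E)[t - tau (1 - e^{-t/tau})]

and past the clamp time ``t_c = sigma0 / a`` the strain decays as a free
Kelvin-Voigt solid, gamma(t) = gamma(t_c) exp(-(t - t_c)/tau).

After the step the trapping power only holds the cell; the trapping stress
is approximated as zero, so the relaxation is the free decay
gamma(T + dt) = gamma(T) exp(-dt/tau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np
from scipy.optimize import least_squares

from .protocols import StretchProtocol

if TYPE_CHECKING:  # pragma: no cover
    from .tracking import AxisTrace

__all__ = [
    "DeformationCurve",
    "KVFit",
    "RestorationResult",
    "stress_from_power",
    "force_from_power",
    "kv_creep",
    "active_kv_creep",
    "kv_relax",
    "relative_deformation",
    "elliptic_deformation",
    "fit_kv",
    "fit_all",
    "shape_restoration",
    "classify_activity",
]

#: Step stress per unit laser power, Pa/mW (0.38 Pa at 400 mW).
STRESS_PER_MW = 0.38 / 400.0
#: Peak stretching force per unit laser power, pN/mW (80 pN at 400 mW).
FORCE_PER_MW = 80.0 / 400.0

#: Fitted-activity threshold separating active from non-active cells, Pa/s.
#: Below it the contraction signal vanishes in the random noise of the fit.
ACTIVITY_THRESHOLD = 1e-3

# fit bounds: E in (0, 1e6] Pa, tau in (1e-3, 1e3] s, a in [0, 10] Pa/s
_E_BOUNDS = (1e-6, 1e6)
_TAU_BOUNDS = (1e-3, 1e3)
_A_BOUNDS = (0.0, 10.0)


def stress_from_power(power_mw: float, coefficient: float = STRESS_PER_MW) -> float:
    """Map laser power (mW) to the applied step stress (Pa), linearly."""
    if np.any(np.asarray(power_mw) < 0):
        raise ValueError("laser power must be >= 0")
    return coefficient * power_mw


def force_from_power(power_mw: float, coefficient: float = FORCE_PER_MW) -> float:
    """Map laser power (mW) to the peak stretching force (pN), linearly."""
    if np.any(np.asarray(power_mw) < 0):
        raise ValueError("laser power must be >= 0")
    return coefficient * power_mw


def _check_kv_params(E: float, eta: float) -> None:
    if E <= 0 or eta <= 0:
        raise ValueError("E and eta must be > 0")


def kv_creep(t, E: float, eta: float, sigma0: float):
    """Passive Kelvin-Voigt creep strain under a step stress.

    gamma(t) = (sigma0/E) (1 - exp(-t/tau)), tau = eta/E.
    """
    _check_kv_params(E, eta)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau = eta / E
    return (sigma0 / E) * (1.0 - np.exp(-t / tau))


def active_kv_creep(t, E: float, eta: float, sigma0: float, a: float):
    """Active Kelvin-Voigt creep strain under a linearly decaying step stress.

    Solves eta gamma' + E gamma = max(sigma0 - a t, 0) with gamma(0) = 0.
    Reduces to :func:`kv_creep` for a = 0.
    """
    _check_kv_params(E, eta)
    if a < 0:
        raise ValueError("activity a must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if a == 0:
        return kv_creep(t, E, eta, sigma0)
    tau = eta / E

    def unclamped(tt):
        decay = 1.0 - np.exp(-tt / tau)
        return (sigma0 / E) * decay - (a / E) * (tt - tau * decay)

    t_clamp = sigma0 / a
    out = unclamped(np.minimum(t, t_clamp))
    past = t > t_clamp
    if np.any(past):
        g_c = unclamped(np.array(t_clamp))
        out = np.where(past, g_c * np.exp(np.minimum(t_clamp - t, 0.0) / tau), out)
    return out if out.ndim else float(out)


def kv_relax(dt_after_stretch, strain_at_end: float, tau: float):
    """Free relaxation after the step: gamma(T+dt) = gamma(T) exp(-dt/tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    dt = np.asarray(dt_after_stretch, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be >= 0")
    return strain_at_end * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# deformation curves


@dataclass
class DeformationCurve:
    """A dimensionless deformation signal over time for one cell.

    ``signal`` is ``"relative"`` (fractional elongation of the long axis)
    or ``"elliptic"`` (change of the long/short axis ratio against the
    resting shape).  ``phase_marks`` are the frame indices of stretch
    start and end, inherited from the source trace.
    """

    time: np.ndarray
    value: np.ndarray
    signal: Literal["relative", "elliptic"]
    phase_marks: tuple[int, int]
    protocol: StretchProtocol
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have the same length")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("deformation values must be finite")

    @property
    def end_of_stretch_value(self) -> float:
        """Deformation at the last stretch-phase frame."""
        return float(self.value[self.phase_marks[1]])


def relative_deformation(trace: "AxisTrace") -> DeformationCurve:
    """Fractional elongation of the long axis, d(t) = (L(t) - L0)/L0.

    The resting length L0 is the mean long axis over the pre-stretch
    (trap-only) window, so the curve averages to zero over the baseline.
    """
    i0 = trace.phase_marks[0]
    if i0 < 1:
        raise ValueError("trace has no pre-stretch baseline frames")
    L0 = float(np.mean(trace.long_um[:i0]))
    if L0 <= 0:
        raise ValueError("baseline long axis must be > 0")
    return DeformationCurve(
        time=trace.time,
        value=trace.long_um / L0 - 1.0,
        signal="relative",
        phase_marks=trace.phase_marks,
        protocol=trace.protocol,
        cell_id=trace.cell_id,
    )


def elliptic_deformation(trace: "AxisTrace") -> DeformationCurve:
    """Change of the long/short axis ratio against the resting shape.

    eps(t) = [L(t)/S(t)] / e0 - 1 with e0 the mean pre-stretch axis ratio.
    Unlike the relative deformation this captures the Poisson effect: the
    short axis contracts while the long axis elongates.
    """
    i0 = trace.phase_marks[0]
    if i0 < 1:
        raise ValueError("trace has no pre-stretch baseline frames")
    if np.any(trace.short_um <= 0):
        raise ValueError("short axis must be > 0")
    ratio = trace.long_um / trace.short_um
    e0 = float(np.mean(ratio[:i0]))
    return DeformationCurve(
        time=trace.time,
        value=ratio / e0 - 1.0,
        signal="elliptic",
        phase_marks=trace.phase_marks,
        protocol=trace.protocol,
        cell_id=trace.cell_id,
    )


# ---------------------------------------------------------------------------
# fitting


def _creep_and_jacobian(t: np.ndarray, E: float, tau: float, sigma0: float, a: float):
    """Active-KV strain and its derivatives w.r.t. (E, tau, a).

    Uses the piecewise closed form; on the clamped branch the chain-rule
    terms through the clamp time t_c = sigma0/a cancel exactly, leaving
    d(gamma)/da = exp(-(t-t_c)/tau) * d(gamma_c)/da.
    """
    t_clamp = sigma0 / a if a > 0 else np.inf
    tm = np.minimum(t, t_clamp)
    expm = np.exp(-tm / tau)
    D = 1.0 - expm
    Dp = -expm * tm / tau**2  # dD/dtau
    g_un = (sigma0 / E) * D - (a / E) * (tm - tau * D)
    dg_dtau = (sigma0 / E) * Dp + (a / E) * (D + tau * Dp)
    dg_da = -(tm - tau * D) / E

    past = t > t_clamp
    if np.any(past):
        decay = np.where(past, np.exp(np.minimum(t_clamp - t, 0.0) / tau), 1.0)
        g = np.where(past, g_un * decay, g_un)
        dg_dtau = np.where(
            past, decay * (dg_dtau + g_un * (t - tm) / tau**2), dg_dtau
        )
        dg_da = np.where(past, decay * dg_da, dg_da)
    else:
        g = g_un
    dg_dE = -g / E
    return g, dg_dE, dg_dtau, dg_da


@dataclass
class KVFit:
    """Result of one Kelvin-Voigt fit to a deformation curve.

    Non-converged fits carry NaN parameters and ``converged=False``; they
    are exported as masked features, never as silent defaults.
    """

    E: float
    eta: float
    tau: float
    a: float
    fit_error: float
    window: Literal["full", "first2s"]
    signal: Literal["relative", "elliptic"]
    model: Literal["passive", "active"]
    converged: bool
    cell_id: str = ""

    @classmethod
    def failed(cls, window: str, signal: str, model: str, cell_id: str = "") -> "KVFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, window, signal, model, False, cell_id)


def _stretch_window(curve: DeformationCurve, window: str):
    i0, i1 = curve.phase_marks
    t = curve.time[i0 : i1 + 1] - curve.time[i0]
    y = curve.value[i0 : i1 + 1]
    if window == "first2s":
        keep = t <= 2.0
        t, y = t[keep], y[keep]
    elif window != "full":
        raise ValueError(f"unknown window {window!r}")
    return t, y


def fit_kv(
    curve: DeformationCurve,
    window: Literal["full", "first2s"] = "full",
    model: Literal["passive", "active"] = "active",
) -> KVFit:
    """Nonlinear least-squares Kelvin-Voigt fit to the stretch phase.

    Trust-region least squares with analytic Jacobian on (E, tau[, a]),
    bounds E in (0, 1e6] Pa, tau in (1e-3, 1e3] s, a in [0, 10] Pa/s,
    initialised at E0 = sigma0/gamma(T), tau0 = 0.3 T, a0 = 0 (well-posed
    fits converge within a few dozen evaluations; the 60-evaluation cap
    only truncates ill-posed fits that end flagged regardless).  The fit
    error is the RMS residual.  Degenerate curves (no measurable
    deformation, E pushed to its bound) are flagged non-converged.
    """
    if model not in ("passive", "active"):
        raise ValueError(f"unknown model {model!r}")
    t, y = _stretch_window(curve, window)
    if t.size < 10:
        raise ValueError("window must contain at least 10 stretch-phase samples")
    sigma0 = curve.protocol.step_stress
    g_end = float(np.mean(y[-5:]))
    # a curve with no measurable deformation leaves E unbounded
    if sigma0 <= 0 or not np.isfinite(g_end) or not np.any(np.abs(y) > 1e-12):
        return KVFit.failed(window, curve.signal, model, curve.cell_id)

    E0 = np.clip(sigma0 / max(g_end, 1e-4), *_E_BOUNDS)
    tau0 = np.clip(0.3 * t[-1], *_TAU_BOUNDS)
    # a second, fast-relaxing start plus one with a head start on activity
    # lets the fit escape the local minima of the clamped active model
    tau_alt = np.clip(0.05 * t[-1], *_TAU_BOUNDS)
    g_peak = float(np.max(y))
    E_peak = np.clip(sigma0 / max(g_peak, 1e-4), *_E_BOUNDS)

    if model == "passive":
        starts = [[E0, tau0], [E0, tau_alt]]
        lo = [_E_BOUNDS[0], _TAU_BOUNDS[0]]
        hi = [_E_BOUNDS[1], _TAU_BOUNDS[1]]

        def resid(x):
            g, *_ = _creep_and_jacobian(t, x[0], x[1], sigma0, 0.0)
            return g - y

        def jac(x):
            _, dE, dtau, _ = _creep_and_jacobian(t, x[0], x[1], sigma0, 0.0)
            return np.column_stack([dE, dtau])

    else:
        a_alt = np.clip(sigma0 / (2 * t[-1]), *_A_BOUNDS)
        starts = [[E0, tau0, 0.0], [E0, tau_alt, 0.0], [E_peak, tau_alt, a_alt]]
        lo = [_E_BOUNDS[0], _TAU_BOUNDS[0], _A_BOUNDS[0]]
        hi = [_E_BOUNDS[1], _TAU_BOUNDS[1], _A_BOUNDS[1]]

        def resid(x):
            g, *_ = _creep_and_jacobian(t, x[0], x[1], sigma0, x[2])
            return g - y

        def jac(x):
            _, dE, dtau, da = _creep_and_jacobian(t, x[0], x[1], sigma0, x[2])
            return np.column_stack([dE, dtau, da])

    # scale parameters to comparable magnitudes so the trust region is
    # well conditioned (E ~ tens of Pa, tau ~ seconds, a ~ 0.01 Pa/s)
    x_scale = [max(E0, 1.0), max(tau0, 0.1)] + ([0.01] if model == "active" else [])
    res = None
    for x0 in starts:
        try:
            cand = least_squares(
                resid, x0, jac=jac, bounds=(lo, hi), method="trf", max_nfev=60,
                ftol=1e-10, x_scale=x_scale,
            )
        except Exception:
            continue
        if res is None or cand.cost < res.cost:
            res = cand
    if res is None:
        return KVFit.failed(window, curve.signal, model, curve.cell_id)

    E, tau = res.x[0], res.x[1]
    a = float(res.x[2]) if model == "active" else float("nan")
    fit_error = float(np.sqrt(np.mean(res.fun**2)))
    # E at its upper bound means the curve carries no deformation signal
    converged = bool(res.status > 0) and E < 0.99 * _E_BOUNDS[1]
    if not converged:
        fit = KVFit.failed(window, curve.signal, model, curve.cell_id)
        fit.fit_error = fit_error
        return fit
    return KVFit(
        E=float(E),
        eta=float(E * tau),
        tau=float(tau),
        a=a,
        fit_error=fit_error,
        window=window,
        signal=curve.signal,
        model=model,
        converged=True,
        cell_id=curve.cell_id,
    )


def fit_all(trace: "AxisTrace") -> list[KVFit]:
    """All eight fits for one cell: 2 signals x 2 windows x 2 models."""
    fits = []
    for make_curve in (relative_deformation, elliptic_deformation):
        curve = make_curve(trace)
        for window in ("full", "first2s"):
            for model in ("passive", "active"):
                fits.append(fit_kv(curve, window=window, model=model))
    return fits


# ---------------------------------------------------------------------------
# shape restoration and activity


@dataclass
class RestorationResult:
    """Shape restoration: elongation lost within 1.5 s of relaxation.

    R = d(T) - d(T + 1.5 s); positive values mean the cell recoils toward
    its original shape (elastic behaviour), values near zero mean viscous,
    dissipative behaviour.
    """

    elongation_end_stretch: float
    elongation_1p5s_after: float

    @property
    def shape_restoration(self) -> float:
        return self.elongation_end_stretch - self.elongation_1p5s_after


RESTORATION_DELAY_S = 1.5


def shape_restoration(curve: DeformationCurve) -> RestorationResult:
    """Difference between the elongation at the end of the step stress and
    1.5 s into the relaxation phase, sampled at the nearest frames."""
    i1 = curve.phase_marks[1]
    t_end = curve.time[i1]
    t_probe = t_end + RESTORATION_DELAY_S
    dt = 0.5 / curve.protocol.frame_rate
    if curve.time[-1] < t_probe - dt:
        raise ValueError("relaxation phase shorter than 1.5 s")
    j = int(np.argmin(np.abs(curve.time - t_probe)))
    return RestorationResult(
        elongation_end_stretch=float(curve.value[i1]),
        elongation_1p5s_after=float(curve.value[j]),
    )


def classify_activity(fit: KVFit, threshold: float = ACTIVITY_THRESHOLD) -> str:
    """Label a cell ``"active"`` when the fitted activity strictly exceeds
    the threshold (default 0.001 Pa/s), ``"non_active"`` otherwise.

    Non-converged or activity-free fits yield ``"undetermined"``.
    """
    if not fit.converged or not np.isfinite(fit.a):
        return "undetermined"
    return "active" if fit.a > threshold else "non_active"
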