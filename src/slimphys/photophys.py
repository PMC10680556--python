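"""Chlorophyll-fluorescence quenching and electrochromic-shift metrics.

Formulas: NPQ = (Fm - Fm')/Fm'; Y(II) = (Fm' - F)/Fm'; Fv/Fm =
(Fm - Fo)/Fm; fast-relaxing NPQ (qE) = NPQ at the light-to-dark
transition minus the minimum NPQ in the dark; ECS = dA520 - dA545
(optionally normalized by ECS_ST); PMF = light-steady ECS minus the
post-light-off minimum; gH+ = 1/tau of a single-exponential fit over
the first 100 ms of decay; vH+ = PMF * gH+; total chlorophyll
(ug/mL) = 22.12 * A652 + 2.71 * A665; specific growth rate
mu = ln(N2/N1)/t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class PhotophysError(ValueError):
    """Raised for non-physical inputs (non-positive denominators etc.)."""


@dataclass
class PAMTrace:
    time: np.ndarray
    fluorescence: np.ndarray
    pulse_times: np.ndarray
    light_on: float
    light_off: float
    Fm: float
    Fo: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.pulse_times = np.sort(np.asarray(self.pulse_times, dtype=float))
        if not self.Fm > 0:
            raise PhotophysError(f"Fm must be > 0; got {self.Fm}")


@dataclass
class ECSTrace:
    time: np.ndarray
    a520: np.ndarray
    a545: np.ndarray
    light_off_time: float
    ecs_st: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a520 = np.asarray(self.a520, dtype=float)
        self.a545 = np.asarray(self.a545, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise PhotophysError("ECS time axis must be strictly increasing")
        if self.ecs_st is not None and not self.ecs_st > 0:
            raise PhotophysError(f"ecs_st must be > 0 when given; got {self.ecs_st}")


@dataclass
class PhotophysResult:
    npq_series: np.ndarray | None = None
    yii_series: np.ndarray | None = None
    pulse_times: np.ndarray | None = None
    fv_fm: float | None = None
    qe_fast: float | None = None
    pmf: float | None = None
    g_h: float | None = None
    v_h: float | None = None
    g_h_valid: bool = True

    def to_dict(self) -> dict:
        def _f(x):
            if x is None:
                return None
            if isinstance(x, np.ndarray):
                return x.tolist()
            return float(x)

        return {
            "npq_series": _f(self.npq_series),
            "yii_series": _f(self.yii_series),
            "pulse_times": _f(self.pulse_times),
            "fv_fm": _f(self.fv_fm),
            "qe_fast": _f(self.qe_fast),
            "pmf": _f(self.pmf),
            "g_h": _f(self.g_h),
            "v_h": _f(self.v_h),
            "g_h_valid": bool(self.g_h_valid),
        }


def npq(Fm: float, Fm_prime: float) -> float:
    """Non-photochemical quenching (Fm - Fm')/Fm'."""
    if not Fm_prime > 0:
        raise PhotophysError(f"Fm' must be > 0; got {Fm_prime}")
    return (Fm - Fm_prime) / Fm_prime


def yii(Fm_prime: float, F: float) -> float:
    """PSII operating quantum yield (Fm' - F)/Fm'."""
    if not Fm_prime > 0:
        raise PhotophysError(f"Fm' must be > 0; got {Fm_prime}")
    return (Fm_prime - F) / Fm_prime


def fv_fm(Fm: float, Fo: float) -> float:
    """Maximal PSII photochemical efficiency (Fm - Fo)/Fm."""
    if not Fm > 0:
        raise PhotophysError(f"Fm must be > 0; got {Fm}")
    return (Fm - Fo) / Fm


def fast_relaxing_npq(npq_series: np.ndarray, light_off_index: int) -> float:
    """qE: NPQ at the light-to-dark transition minus the dark minimum.

    ``light_off_index`` is the index of the last pulse in the light;
    later pulses are the dark-relaxation phase.
    """
    series = np.asarray(npq_series, dtype=float)
    if not 0 <= light_off_index < series.size:
        raise PhotophysError(f"light_off_index {light_off_index} outside series")
    dark = series[light_off_index + 1 :]
    if dark.size == 0:
        raise PhotophysError("no pulses after the light-to-dark transition")
    return float(series[light_off_index] - dark.min())


def pam_metrics(trace: PAMTrace, pulse_window: float = 1.0) -> PhotophysResult:
    """Per-pulse NPQ and Y(II) series plus Fv/Fm from a PAM record.

    ``Fm'`` is the maximum fluorescence within ``pulse_window`` seconds
    after each pulse; ``F`` (stationary) is the value just before it.
    """
    npq_vals, yii_vals, kept = [], [], []
    for pt in trace.pulse_times:
        sel = (trace.time >= pt) & (trace.time < pt + pulse_window)
        pre = trace.time < pt
        if not sel.any():
            continue
        fm_prime = float(trace.fluorescence[sel].max())
        f_stat = float(trace.fluorescence[pre][-1]) if pre.any() else float(
            trace.fluorescence[sel][0]
        )
        npq_vals.append(npq(trace.Fm, fm_prime))
        yii_vals.append(yii(fm_prime, f_stat))
        kept.append(pt)
    return PhotophysResult(
        npq_series=np.asarray(npq_vals),
        yii_series=np.asarray(yii_vals),
        pulse_times=np.asarray(kept),
        fv_fm=fv_fm(trace.Fm, trace.Fo),
    )


def ecs_signal(trace: ECSTrace) -> np.ndarray:
    """Dual-wavelength ECS series, ECS_ST-normalized when available."""
    signal = trace.a520 - trace.a545
    if trace.ecs_st is not None:
        signal = signal / trace.ecs_st
    return signal


def pmf(
    trace: ECSTrace,
    light_window: float = 0.100,
    dark_window: float = 0.300,
) -> float:
    """PMF size: light-steady ECS minus the post-light-off minimum.

    The light value is the mean over the final ``light_window`` seconds
    of illumination; the dark value the minimum over ``dark_window``
    seconds after light-off.
    """
    t0 = trace.light_off_time
    if not trace.time[0] <= t0 <= trace.time[-1]:
        raise PhotophysError(f"light_off_time {t0} outside record")
    signal = ecs_signal(trace)
    light = (trace.time >= t0 - light_window) & (trace.time < t0)
    dark = (trace.time >= t0) & (trace.time <= t0 + dark_window)
    if not light.any() or not dark.any():
        raise PhotophysError("too few samples around light-off for PMF")
    return float(signal[light].mean() - signal[dark].min())


def g_h(
    trace: ECSTrace,
    fit_window: float = 0.100,
    min_samples: int = 10,
) -> tuple[float, bool]:
    """Proton conductivity gH+ = 1/tau of the first-100-ms ECS decay.

    Least-squares fit of ``offset + A * exp(-(t - t0)/tau)`` over
    ``[light_off, light_off + fit_window]``.  Returns ``(g_h, valid)``;
    the fit is flagged invalid on non-convergence, non-positive tau, or
    an essentially flat signal.
    """
    t0 = trace.light_off_time
    signal = ecs_signal(trace)
    sel = (trace.time >= t0) & (trace.time <= t0 + fit_window)
    if sel.sum() < min_samples:
        raise PhotophysError(
            f"only {int(sel.sum())} samples within {fit_window*1e3:.0f} ms of "
            f"light-off; need >= {min_samples}"
        )
    t = trace.time[sel] - t0
    y = signal[sel]
    drop = float(y[0] - y[-1])
    scale = max(abs(y).max(), 1e-12)
    if abs(drop) < 1e-6 * scale or np.ptp(y) == 0:
        return float("nan"), False

    def model(tt, amp, tau, offset):
        return offset + amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(drop, fit_window / 2.0, float(y[-1])),
            maxfev=10000,
        )
    except RuntimeError:
        return float("nan"), False
    tau = float(popt[1])
    if not np.isfinite(tau) or tau <= 0:
        return float("nan"), False
    return 1.0 / tau, True


def v_h(pmf_value: float, g_h_value: float) -> float:
    """Proton flux vH+ = PMF * gH+."""
    return pmf_value * g_h_value


def ecs_metrics(trace: ECSTrace, **kwargs) -> PhotophysResult:
    """PMF, gH+ and vH+ from one ECS record."""
    pmf_value = pmf(trace)
    gh_value, valid = g_h(trace, **kwargs)
    return PhotophysResult(
        pmf=pmf_value,
        g_h=gh_value if valid else None,
        v_h=v_h(pmf_value, gh_value) if valid else None,
        g_h_valid=valid,
    )


def total_chlorophyll(a652: float, a665: float) -> float:
    """Total chlorophyll (ug/mL) = 22.12 * A652 + 2.71 * A665."""
    if a652 < 0 or a665 < 0:
        raise PhotophysError(f"absorbances must be >= 0; got {a652}, {a665}")
    return 22.12 * a652 + 2.71 * a665


def specific_growth_rate(n1: float, n2: float, t: float) -> float:
    """Specific growth rate mu = ln(N2/N1)/t (per unit of t)."""
    if n1 <= 0 or n2 <= 0 or t <= 0:
        raise PhotophysError(f"need n1, n2, t > 0; got {n1}, {n2}, {t}")
    return float(np.log(n2 / n1) / t)


def dpsi_dph_fractions(
    trace: ECSTrace,
    dark_steady_window: float = 0.100,
) -> tuple[float, float]:
    """Steady-state-dark-point decomposition of the PMF.

    dPsi fraction = (light steady - dark steady)/PMF, dpH fraction its
    complement, where the dark steady level is the mean over the final
    ``dark_steady_window`` seconds of the record.  Reduced-fidelity
    convenience; both fractions are returned ``(dpsi, dph)``.
    """
    signal = ecs_signal(trace)
    total = pmf(trace)
    if total == 0:
        raise PhotophysError("PMF is zero; partition undefined")
    light = (trace.time >= trace.light_off_time - 0.100) & (
        trace.time < trace.light_off_time
    )
    tail = trace.time >= trace.time[-1] - dark_steady_window
    dpsi = float((signal[light].mean() - signal[tail].mean()) / total)
    return dpsi, 1.0 - dpsi
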