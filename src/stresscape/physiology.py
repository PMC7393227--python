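"""PAM-fluorometry physiology calculators.

PSII maximal photochemical quantum yield F_V/F_M = (F_M - F_0)/F_M, percent-
of-initial normalisation of yield time courses, exponential photoinhibition
fitting, short- and long-term PSII repair-rate proxies from paired
control/lincomycin series, and phycobilisome emission-peak ratio extraction
(PE/PC and PC/TA).

The repair-rate proxy rests on the lincomycin logic: with protein synthesis
blocked, damaged D1 cannot be replaced, so the inhibited arm's fluorescence
decay reflects gross photodamage while the control arm's reflects damage net
of repair.  The difference of the decay coefficients (short-term, exponential
fits over a 6 h stress) or of the linear decline slopes (long-term protocol,
15/30/60 min aliquots) estimates the repair rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from stresscape.synthetic import FluorescenceSeries

__all__ = [
    "QuantumYield",
    "RepairRate",
    "SpectrumRatios",
    "compute_fvfm",
    "percent_of_initial",
    "fit_exp_decay",
    "repair_rate_short",
    "repair_rate_long",
    "spectrum_ratios",
    "PE_WINDOW_NM",
    "PC_WINDOW_NM",
    "TA_WINDOW_NM",
]


@dataclass(frozen=True)
class QuantumYield:
    """Basal (F_0) and maximal (F_M) fluorescence with the derived yield."""

    f0: float
    fm: float
    fvfm: float


@dataclass(frozen=True)
class ExpFit:
    """Exponential decay fit y = a * exp(-k t)."""

    a: float
    k: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class RepairRate:
    """PSII repair-rate proxy: difference of decay coefficients between the
    lincomycin-inhibited and control arms (per hour; positive = repair
    active)."""

    k_control: float
    k_inhibited: float
    rate: float
    sse_control: float = 0.0
    sse_inhibited: float = 0.0
    converged: bool = True


@dataclass(frozen=True)
class SpectrumRatios:
    """Window-maximum heights of the PE, PC and terminal-acceptor emission
    peaks and the ratios that report phycobilisome energy-transfer coupling
    (PE/PC within the rods, PC/TA from rods to the reaction center)."""

    pe_height: float
    pc_height: float
    ta_height: float
    pe_pc: float
    pc_ta: float


def compute_fvfm(f0: float, fm: float) -> float:
    """PSII quantum yield (F_M - F_0) / F_M.

    F_0 is the basal fluorescence of dark-acclimated cells under modulated
    light; F_M the maximum under a saturating pulse with the PSII blocker
    DCMU.  Raises if F_M <= 0 or the signal is inverted (F_0 > F_M).
    """
    if fm <= 0:
        raise ValueError(f"F_M must be > 0, got {fm}")
    if f0 > fm:
        raise ValueError(
            f"signal inversion: F_0 ({f0}) exceeds F_M ({fm}); "
            "check dark acclimation / saturating pulse"
        )
    return (fm - f0) / fm


def percent_of_initial(values: np.ndarray) -> np.ndarray:
    """Express a series as percent of its first value (first element = 100)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if values[0] <= 0:
        raise ValueError("first value must be > 0 to normalize")
    return values * 100.0 / values[0]


def fit_exp_decay(times: np.ndarray, values: np.ndarray) -> ExpFit:
    """Nonlinear least-squares fit of y = a * exp(-k t); returns k per hour.

    The initial guess comes from a log-linear regression on the positive
    points; when fewer than two points are positive a coarse grid of decay
    rates seeds the optimizer instead.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise ValueError("need >= 3 time points to fit a decay")
    pos = values > 0
    if pos.sum() >= 2 and np.ptp(times[pos]) > 0:
        slope, intercept, *_ = stats.linregress(times[pos], np.log(values[pos]))
        k0, a0 = max(-slope, 0.0), float(np.exp(intercept))
    else:
        k0, a0 = 1.0, max(values.max(), 1e-6)

    def model(t, a, k):
        return a * np.exp(-k * t)

    seeds = [(a0, k0)] + [(a0, k) for k in (0.0, 0.1, 0.5, 2.0) if k != k0]
    best: ExpFit | None = None
    for a_s, k_s in seeds:
        try:
            popt, _ = optimize.curve_fit(
                model, times, values, p0=[a_s, k_s], maxfev=5000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(times, *popt) - values) ** 2))
        fit = ExpFit(a=float(popt[0]), k=float(popt[1]), sse=sse, converged=True)
        if best is None or sse < best.sse - 1e-15:
            best = fit
        if best.sse < 1e-12:
            break
    if best is None:
        raise RuntimeError("exponential fit failed to converge from all seeds")
    return best


def repair_rate_short(
    control: FluorescenceSeries, inhibited: FluorescenceSeries
) -> RepairRate:
    """Short-term (6 h stress) repair-rate proxy.

    Exponential decay coefficients are fitted to each arm's F_V/F_M time
    course; the repair rate is k_inhibited - k_control.
    """
    fit_c = fit_exp_decay(control.times, control.values)
    fit_i = fit_exp_decay(inhibited.times, inhibited.values)
    return RepairRate(
        k_control=fit_c.k,
        k_inhibited=fit_i.k,
        rate=fit_i.k - fit_c.k,
        sse_control=fit_c.sse,
        sse_inhibited=fit_i.sse,
        converged=fit_c.converged and fit_i.converged,
    )


def repair_rate_long(
    times: np.ndarray,
    control_values: np.ndarray,
    inhibited_values: np.ndarray,
) -> RepairRate:
    """Long-term protocol repair-rate proxy (aliquots at 0, 15, 30, 60 min).

    Each arm's replicate measurements are regressed linearly on time over the
    one-hour window (three points under-determine a two-parameter exponential
    with noise, so the decline is summarized by its slope); the repair rate
    is the slope difference control - inhibited, i.e. the extra decline when
    repair is blocked, positive when repair is active.

    ``control_values`` and ``inhibited_values`` are arrays of shape
    (replicates, len(times)) or (len(times),).
    """
    times = np.asarray(times, dtype=float)
    if len(np.unique(times)) < 3:
        raise ValueError("need >= 3 distinct time points per arm")
    slopes = []
    sses = []
    for arr in (control_values, inhibited_values):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[1] != len(times):
            raise ValueError("values do not match the time grid")
        t_rep = np.tile(times, arr.shape[0])
        y = arr.ravel()
        slope, intercept, *_ = stats.linregress(t_rep, y)
        slopes.append(float(slope))
        sses.append(float(np.sum((intercept + slope * t_rep - y) ** 2)))
    k_control, k_inhibited = -slopes[0], -slopes[1]  # decline rates
    return RepairRate(
        k_control=k_control,
        k_inhibited=k_inhibited,
        rate=k_inhibited - k_control,
        sse_control=sses[0],
        sse_inhibited=sses[1],
    )


# Emission windows (nm): phycoerythrin and phycocyanin maxima ranges, and the
# phycobilisome terminal acceptor at 680 nm read from a +/- 5 nm window.
PE_WINDOW_NM = (565.0, 575.0)
PC_WINDOW_NM = (645.0, 655.0)
TA_WINDOW_NM = (675.0, 685.0)


def _window_max(wavelengths: np.ndarray, intensities: np.ndarray,
                window: tuple[float, float]) -> float:
    lo, hi = window
    if wavelengths.min() > lo or wavelengths.max() < hi:
        raise ValueError(f"spectrum grid does not cover the {lo}-{hi} nm window")
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no grid points inside the {lo}-{hi} nm window")
    return float(intensities[mask].max())


def spectrum_ratios(wavelengths: np.ndarray, intensities: np.ndarray) -> SpectrumRatios:
    """Extract PE, PC and terminal-acceptor peak heights and their ratios.

    Heights are window maxima (PE 565-575 nm, PC 645-655 nm, TA 680 +/- 5
    nm).  A zero denominator makes the corresponding ratio undefined and
    raises, since a vanished peak means the ratio no longer measures
    energy-transfer coupling.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    pe = _window_max(wavelengths, intensities, PE_WINDOW_NM)
    pc = _window_max(wavelengths, intensities, PC_WINDOW_NM)
    ta = _window_max(wavelengths, intensities, TA_WINDOW_NM)
    floor = 1e-9 * max(intensities.max(), 1e-300)  # numerically vanished peak
    if pc <= floor:
        raise ValueError("PC peak height is zero: PE/PC and PC/TA undefined")
    if ta <= floor:
        raise ValueError("terminal-acceptor peak height is zero: PC/TA undefined")
    return SpectrumRatios(
        pe_height=pe, pc_height=pc, ta_height=ta, pe_pc=pe / pc, pc_ta=pc / ta
    )
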