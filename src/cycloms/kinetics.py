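"""Protease-inhibition assay fitting: velocities, dose–response, decay.

The fluorogenic POP assay reads RFU over time in 3-minute intervals.  The
initial velocity is the slope over the first interval after background
correction, percent remaining activity is v_i/v_0 × 100, and the IC50
comes from a four-parameter logistic constrained to bottom 0 / top 100:

    remaining(c) = 100 / (1 + 10^((log10 c − log10 IC50) · h))

Peptide-stability time courses (percent intact vs hours) are fitted with a
one-phase decay y = 100·exp(−k t), giving the half-life ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = [
    "KineticTrace",
    "DoseResponseCurve",
    "FourPLFit",
    "DecayFit",
    "initial_velocity",
    "percent_inhibition",
    "curve_from_traces",
    "fit_4pl",
    "fit_decay",
    "rank_extracts",
]


@dataclass
class KineticTrace:
    """One well's fluorescence time course."""

    well: str
    sample: str
    concentration: float  # µg/mL or µM; units are the caller's convention
    times: list[float]  # minutes, strictly increasing
    rfu: list[float]

    def __post_init__(self):
        if len(self.times) < 2 or len(self.times) != len(self.rfu):
            raise ValueError("need >= 2 matched (time, RFU) readings")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")


@dataclass
class DoseResponseCurve:
    """Per-concentration percent remaining activity (mean, SD, n)."""

    concentrations: list[float]
    mean_activity: list[float]
    sd_activity: list[float] = None
    n: list[int] = None

    def __post_init__(self):
        m = len(self.concentrations)
        if len(self.mean_activity) != m:
            raise ValueError("ragged dose-response data")
        if self.sd_activity is None:
            self.sd_activity = [0.0] * m
        if self.n is None:
            self.n = [1] * m
        if any(k < 1 for k in self.n):
            raise ValueError("n must be >= 1 per point")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")


@dataclass
class FourPLFit:
    """Constrained 4PL fit result (bottom 0, top 100 fixed)."""

    ic50: float
    ic50_sd: float
    hill: float
    hill_sd: float
    sse: float
    converged: bool
    in_tested_range: bool
    message: str = ""


@dataclass
class DecayFit:
    """One-phase decay fit result (plateau fixed at 0)."""

    k: float  # 1/h
    half_life: float  # h
    k_sd: float
    sse: float
    plateau: float = 0.0


def initial_velocity(
    trace: KineticTrace,
    background: KineticTrace | None = None,
    discard_first: bool = False,
) -> float:
    """Slope (RFU/min) over the first time interval.

    ``background`` (a substrate-only control) is subtracted point-wise
    before the slope is taken.  ``discard_first`` drops the t0 read to
    skip a lag phase.
    """
    times = list(trace.times)
    rfu = list(trace.rfu)
    if background is not None:
        if list(background.times) != times:
            raise ValueError("background trace must share the time grid")
        rfu = [a - b for a, b in zip(rfu, background.rfu)]
    if discard_first:
        times, rfu = times[1:], rfu[1:]
        if len(times) < 2:
            raise ValueError("too few readings after discarding the first")
    return (rfu[1] - rfu[0]) / (times[1] - times[0])


def percent_inhibition(v_i: float, v_0: float) -> tuple[float, bool]:
    """Percent inhibition = 100 − v_i/v_0 × 100.

    Returns ``(inhibition, clipped)`` where ``clipped`` flags values that
    fell outside [0, 100] before reporting (noise can push remaining
    activity above the uninhibited control).  The returned value itself is
    not clipped.
    """
    if v_0 <= 0:
        raise ValueError(f"uninhibited velocity must be positive, got {v_0}")
    remaining = v_i / v_0 * 100.0
    inhibition = 100.0 - remaining
    return inhibition, not 0.0 <= inhibition <= 100.0


def curve_from_traces(
    traces: list[KineticTrace],
    discard_first: bool = False,
) -> DoseResponseCurve:
    """Assemble a dose–response curve from raw plate traces.

    Traces with sample ``substrate_control`` define the background (mean
    trace), ``max_activity`` wells define v0, and the remaining wells are
    grouped by concentration into percent remaining activity.
    """
    background = [t for t in traces if t.sample == "substrate_control"]
    maxima = [t for t in traces if t.sample == "max_activity"]
    samples = [t for t in traces if t.sample not in ("substrate_control", "max_activity")]
    if not maxima or not samples:
        raise ValueError("need max_activity wells and sample wells")
    bg = None
    if background:
        grid = background[0].times
        mean_rfu = np.mean([t.rfu for t in background], axis=0)
        bg = KineticTrace("BG", "substrate_control", 0.0, list(grid), list(mean_rfu))
    v0 = float(
        np.mean([initial_velocity(t, bg, discard_first) for t in maxima])
    )
    if v0 <= 0:
        raise ValueError("non-positive uninhibited velocity")
    by_conc: dict[float, list[float]] = {}
    for t in samples:
        v = initial_velocity(t, bg, discard_first)
        by_conc.setdefault(t.concentration, []).append(v / v0 * 100.0)
    concs = sorted(by_conc)
    return DoseResponseCurve(
        concentrations=concs,
        mean_activity=[float(np.mean(by_conc[c])) for c in concs],
        sd_activity=[float(np.std(by_conc[c], ddof=1)) if len(by_conc[c]) > 1 else 0.0
                     for c in concs],
        n=[len(by_conc[c]) for c in concs],
    )


def _four_pl(logc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** ((logc - log_ic50) * hill))


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares constrained 4PL fit of remaining activity vs log10 c.

    Fitted in log10-IC50 space for numerical stability; the IC50 SD is
    propagated with the delta method.  Non-convergence is reported in the
    result (``converged=False``), never silently replaced.
    """
    c = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.mean_activity, dtype=float)
    if len(set(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations for a 4PL fit")
    logc = np.log10(c)
    p0 = [float(np.median(logc)), 1.0]
    try:
        popt, pcov = curve_fit(_four_pl, logc, y, p0=p0, maxfev=20000)
        converged, message = True, ""
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                         False, False, message=str(exc))
    log_ic50, hill = popt
    perr = np.sqrt(np.diag(pcov))
    ic50 = 10.0 ** log_ic50
    ic50_sd = math.log(10) * ic50 * perr[0]
    resid = y - _four_pl(logc, *popt)
    return FourPLFit(
        ic50=ic50,
        ic50_sd=float(ic50_sd),
        hill=float(hill),
        hill_sd=float(perr[1]),
        sse=float(np.sum(resid**2)),
        converged=converged,
        in_tested_range=bool(c.min() <= ic50 <= c.max()),
        message=message,
    )


def fit_decay(times_h, percent_remaining) -> DecayFit:
    """Fit y = 100·exp(−k t) to a stability time course (t in hours)."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(percent_remaining, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 time points")
    if y[-1] > y[0]:
        raise ValueError("series increases over time; not a decay")

    def model(t, k):
        return 100.0 * np.exp(-k * t)

    # log-linear initial guess from positive readings
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos] / 100.0), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 0.1
    popt, pcov = curve_fit(model, t, y, p0=[k0], maxfev=20000)
    k = float(popt[0])
    if k <= 0:
        raise ValueError(f"fitted rate non-positive ({k}); not a decay")
    resid = y - model(t, k)
    return DecayFit(
        k=k,
        half_life=math.log(2) / k,
        k_sd=float(np.sqrt(pcov[0, 0])),
        sse=float(np.sum(resid**2)),
    )


def rank_extracts(
    ic50s: dict[str, float], peptide_counts: dict[str, int]
) -> tuple[pd.DataFrame, float]:
    """Rank extracts by potency and correlate with peptide content.

    Returns the table sorted by IC50 ascending (most potent first) and the
    Spearman rank correlation between peptide count and IC50.  Sign
    convention: more peptides associated with *lower* IC50 (higher
    potency) gives a negative rho; rho = −1 for perfect concordance.
    """
    if len(ic50s) < 3:
        raise ValueError("need >= 3 extracts")
    if set(ic50s) != set(peptide_counts):
        raise ValueError("extract names must match between inputs")
    names = sorted(ic50s, key=lambda n: ic50s[n])
    table = pd.DataFrame(
        {
            "extract": names,
            "ic50": [ic50s[n] for n in names],
            "n_peptides": [peptide_counts[n] for n in names],
        }
    )
    rho = spearmanr(table["n_peptides"], table["ic50"]).statistic
    return table, float(rho)
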