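"""DPPH radical-scavenging quantification and bioconversion kinetics.

DPPH is a stable radical whose 515 nm absorbance (epsilon = 12 mM^-1 cm^-1
in methanol) disappears on reduction.  The assay mathematics implemented
here:

  %DPPHred = [1 - [DPPH](t_end)/[DPPH](0)] * 100      (t_end = 30 min)
  EC50     = antioxidant/DPPH molar ratio giving 50% reduction, from a
             non-linear (Hill) regression of the dose-response curve
  TEC50    = minutes to reach a stable absorbance at the EC50 ratio
  AE       = 1/(EC50 * TEC50), the antiradical efficiency

Bioconversion analytics: product formation rates from the initial linear
window of an HPLC time course, molar yield (total product / starting
substrate) and product distribution at a chosen time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, PlateauError, RangeError

EXTINCTION_515 = 12.0   # mM^-1 cm^-1, DPPH in methanol


@dataclass
class KineticTrace:
    """Absorbance-vs-time trace of a single DPPH reaction mixture."""
    times: np.ndarray               # minutes, strictly increasing
    absorbance_515: np.ndarray      # AU
    antioxidant_ratio: float        # uM antioxidant / uM DPPH
    dpph_initial: float = 100.0     # uM
    extinction_515: float = EXTINCTION_515
    path_length: float = 1.0        # cm
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance_515 = np.asarray(self.absorbance_515, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.absorbance_515.shape:
            raise ValueError("times and absorbance must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.absorbance_515 < 0):
            raise ValueError("absorbance must be non-negative")
        if self.dpph_initial <= 0:
            raise ValueError("dpph_initial must be positive")

    def dpph_concentration(self) -> np.ndarray:
        """[DPPH] in uM from A = eps * l * [DPPH](mM)."""
        return self.absorbance_515 / (self.extinction_515 * self.path_length) * 1000.0


@dataclass
class DoseResponse:
    """%DPPHred as a function of the antioxidant/DPPH molar ratio."""
    ratios: np.ndarray
    percent_reduced: np.ndarray     # clipped to [0, 100]; raw values retained
    replicate_ids: np.ndarray | None = None
    raw_percent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        raw = np.asarray(self.percent_reduced, dtype=float)
        self.raw_percent = raw
        self.percent_reduced = np.clip(raw, 0.0, 100.0)
        if self.replicate_ids is None:
            self.replicate_ids = np.zeros(len(self.ratios), dtype=int)


@dataclass
class AntioxidantResult:
    ec50: float                     # uM/uM
    tec50: float                    # minutes
    ae: float                       # (uM/uM * min)^-1
    sse: float = np.nan
    n: int = 0
    hill_n: float = np.nan
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.ec50) and np.isfinite(self.tec50):
            expected = 1.0 / (self.ec50 * self.tec50)
            if abs(self.ae - expected) > 1e-12 * max(1.0, abs(expected)):
                raise ValueError("ae must equal 1/(ec50*tec50)")


@dataclass
class TimeCourse:
    """Product concentrations (uM) vs time (min) for one biotransformation."""
    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    substrate_initial: float        # uM
    substrate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.concentrations = {k: np.asarray(v, dtype=float)
                               for k, v in self.concentrations.items()}
        for k, v in self.concentrations.items():
            if v.shape != self.times.shape:
                raise ValueError(f"product {k}: concentration length mismatch")
            if np.any(v < -1e-9):
                raise ValueError(f"product {k}: negative concentration")
        if self.substrate_initial <= 0:
            raise ValueError("substrate_initial must be positive")


# ---------------------------------------------------------------------------
# DPPH quantification
# ---------------------------------------------------------------------------

def percent_dpph_reduced(trace: KineticTrace, t_end: float = 30.0) -> float:
    """%DPPHred at `t_end` minutes (linear interpolation between samples)."""
    if t_end < trace.times[0] or t_end > trace.times[-1]:
        raise RangeError(f"t_end={t_end} outside sampled range "
                         f"[{trace.times[0]}, {trace.times[-1]}]")
    conc = trace.dpph_concentration()
    c0 = conc[0]
    ct = float(np.interp(t_end, trace.times, conc))
    if c0 <= 0:
        raise ValueError("initial DPPH absorbance is zero")
    return (1.0 - ct / c0) * 100.0


@dataclass
class EC50Fit:
    ec50: float
    hill_n: float
    sse: float
    n_obs: int
    model: str = "hill"
    extrapolated: bool = False


def _hill(r, ec50, n):
    r = np.asarray(r, dtype=float)
    return 100.0 * r ** n / (ec50 ** n + r ** n)


def _clipped_linear(r, ec50):
    """Stoichiometric titration curve: linear through the origin, clipped at
    100%; crosses 50% exactly at r = EC50."""
    r = np.asarray(r, dtype=float)
    return np.minimum(100.0, 50.0 * r / ec50)


def fit_ec50(data: DoseResponse) -> EC50Fit:
    """Non-linear least-squares EC50 from a dose-response curve.

    Two saturating candidate models are fitted and the better one (smaller
    SSE) reported: the Hill form %red = 100 r^n / (EC50^n + r^n) with the
    exponent free in [0.5, 6], and the clipped-linear stoichiometric form
    %red = min(100, 50 r / EC50) produced by fast complete consumption of
    the radical (equal SSE prefers Hill).  In both, the reported EC50 is
    the ratio at which the fitted curve equals 50%.

    Needs >= 4 distinct ratios.  If the observed responses never cross 50%,
    the result is returned with ``extrapolated=True`` and a warning.
    """
    r = data.ratios
    y = data.percent_reduced
    if len(np.unique(r)) < 4:
        raise ValueError("need at least 4 distinct antioxidant ratios")
    crossing = y.min() < 50.0 < y.max()
    if not crossing:
        warnings.warn("dose-response does not cross 50%; EC50 is an extrapolation")
    # initial guess: ratio whose response is closest to 50%
    r0 = float(r[np.argmin(np.abs(y - 50.0))])
    try:
        popt, _ = optimize.curve_fit(_hill, r, y, p0=[max(r0, 1e-3), 1.0],
                                     bounds=([1e-6, 0.5], [1e3, 6.0]), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"EC50 regression failed to converge: {exc}") from exc
    ec50_h, n = float(popt[0]), float(popt[1])
    sse_h = float(np.sum((y - _hill(r, ec50_h, n)) ** 2))

    res = optimize.minimize_scalar(
        lambda e: float(np.sum((y - _clipped_linear(r, e)) ** 2)),
        bounds=(1e-6, 1e3), method="bounded",
        options={"xatol": 1e-10})
    ec50_l, sse_l = float(res.x), float(res.fun)

    if sse_l < sse_h:
        return EC50Fit(ec50=ec50_l, hill_n=np.nan, sse=sse_l, n_obs=len(r),
                       model="clipped_linear", extrapolated=not crossing)
    return EC50Fit(ec50=ec50_h, hill_n=n, sse=sse_h, n_obs=len(r),
                   model="hill", extrapolated=not crossing)


def tec50(trace: KineticTrace, plateau_tol: float = 0.01,
          window: float | None = None) -> float:
    """Minutes to reach a stable absorbance: first sampled time at which the
    fitted exponential decay A(t) = Af + (A0-Af) exp(-t/tau) is within
    `plateau_tol` of its asymptote (relative to the total drop A0-Af).

    `window` optionally restricts the fit to times <= window.  Raises
    PlateauError when the trace has no decaying plateau (e.g. is monotone
    increasing, or the exponential fits no better than a straight line).
    """
    t = trace.times
    a = trace.absorbance_515
    if window is not None:
        keep = t <= window
        t, a = t[keep], a[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    t0 = t - t[0]
    drop = a[0] - a[-1]
    scale = max(abs(a).max(), 1e-12)
    if abs(drop) < 1e-9 * scale and np.ptp(a) < 1e-9 * scale:
        return float(t[0])          # already stable
    if drop < 0:
        raise PlateauError("absorbance increases; no reduction plateau")

    def model(tt, af, a0, tau):
        return af + (a0 - af) * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t0, a, p0=[a[-1], a[0], max(t0[-1] / 5.0, 1e-3)],
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise PlateauError(f"no exponential plateau detected: {exc}") from exc
    af, a0f, tau = (float(v) for v in popt)
    sse_exp = float(np.sum((a - model(t0, *popt)) ** 2))
    lin = np.polyfit(t0, a, 1)
    sse_lin = float(np.sum((a - np.polyval(lin, t0)) ** 2))
    if a0f <= af or sse_exp > sse_lin * (1.0 + 1e-9):
        raise PlateauError("exponential-to-plateau fit no better than linear; "
                           "no plateau detected")
    t_cross = tau * np.log(1.0 / plateau_tol)
    idx = int(np.searchsorted(t0, t_cross - 1e-9))
    if idx >= len(t):
        raise PlateauError("plateau not reached within the trace")
    return float(t[idx])


def antiradical_efficiency(ec50: float, tec50_min: float) -> float:
    """AE = 1/(EC50 * TEC50)."""
    if not (np.isfinite(ec50) and np.isfinite(tec50_min)):
        raise ValueError("EC50 and TEC50 must be finite")
    if ec50 <= 0 or tec50_min <= 0:
        raise ValueError("EC50 and TEC50 must be positive")
    return 1.0 / (ec50 * tec50_min)


def antioxidant_summary(results: list[AntioxidantResult]) -> dict[str, float]:
    """Aggregate replicate results under both AE conventions: the mean of
    per-replicate AE values, and AE of the mean EC50/TEC50."""
    ec = np.array([r.ec50 for r in results])
    tc = np.array([r.tec50 for r in results])
    ae = np.array([r.ae for r in results])
    return {
        "ec50_mean": float(ec.mean()), "ec50_sd": float(ec.std(ddof=1)) if len(ec) > 1 else 0.0,
        "tec50_mean": float(tc.mean()), "tec50_sd": float(tc.std(ddof=1)) if len(tc) > 1 else 0.0,
        "ae_per_replicate_mean": float(ae.mean()),
        "ae_of_means": antiradical_efficiency(float(ec.mean()), float(tc.mean())),
        "n": len(results),
    }


# ---------------------------------------------------------------------------
# Bioconversion kinetics
# ---------------------------------------------------------------------------

@dataclass
class RateFit:
    rate: float                     # uM/min
    intercept: float
    r_squared: float
    stderr: float
    window_end: float               # last time in the fitted window
    n: int
    flags: list[str] = field(default_factory=list)


def formation_rate(tc: TimeCourse, product: str,
                   window: float | None = None, r2_min: float = 0.999) -> RateFit:
    """OLS slope of product concentration vs time over the initial linear
    window.  When `window` is None it is chosen automatically as the longest
    initial span whose linear fit has R^2 >= `r2_min` (the maximum time over
    which accumulation is still proportional to incubation time)."""
    t = tc.times
    y = tc.concentrations[product]
    if window is not None:
        keep = t <= window
        t, y = t[keep], y[keep]
        if len(t) < 2:
            raise ValueError("window contains fewer than 2 points")
    flags: list[str] = []
    if window is None:
        best = 3
        if len(t) < 3:
            best = len(t)
        else:
            for k in range(len(t), 2, -1):
                res = stats.linregress(t[:k], y[:k])
                if res.rvalue ** 2 >= r2_min or np.allclose(y[:k], y[0]):
                    best = k
                    break
        t, y = t[:best], y[:best]
    if len(t) == 2:
        flags.append("two-point fit: no degrees of freedom for diagnostics")
        rate = float((y[1] - y[0]) / (t[1] - t[0]))
        return RateFit(rate=rate, intercept=float(y[0] - rate * t[0]), r_squared=1.0,
                       stderr=np.nan, window_end=float(t[-1]), n=2, flags=flags)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    if res.slope < 0 and np.isfinite(res.stderr) and res.slope < -2.0 * res.stderr:
        flags.append("negative formation rate beyond noise")
        warnings.warn(f"{product}: fitted formation rate is negative")
    return RateFit(rate=float(res.slope), intercept=float(res.intercept),
                   r_squared=r2, stderr=float(res.stderr),
                   window_end=float(t[-1]), n=len(t), flags=flags)


def yield_and_distribution(tc: TimeCourse, t: float) -> tuple[float, dict[str, float]]:
    """Total molar yield (%) and per-product distribution (%) at time `t`.

    yield = 100 * sum of product concentrations / initial substrate;
    distribution_i = 100 * c_i / total products (sums to 100).
    """
    if t < tc.times[0] or t > tc.times[-1]:
        raise RangeError(f"t={t} outside sampled range")
    at_t = {k: float(np.interp(t, tc.times, v)) for k, v in tc.concentrations.items()}
    total = sum(at_t.values())
    if total <= 0:
        raise ZeroDivisionError("zero total product; distribution undefined")
    total_yield = 100.0 * total / tc.substrate_initial
    distribution = {k: 100.0 * v / total for k, v in at_t.items()}
    return total_yield, distribution


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def load_traces(path, **trace_kwargs) -> list[KineticTrace]:
    """Read traces from CSV columns time_min,abs515,ratio,replicate."""
    df = pd.read_csv(path, comment="#")
    traces = []
    for (ratio, rep), grp in df.groupby(["ratio", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(KineticTrace(times=grp["time_min"].to_numpy(),
                                   absorbance_515=grp["abs515"].to_numpy(),
                                   antioxidant_ratio=float(ratio),
                                   replicate_id=int(rep), **trace_kwargs))
    return traces


def load_dose_response(path) -> DoseResponse:
    """Read a dose-response table from CSV columns ratio,percent_reduced[,replicate]."""
    df = pd.read_csv(path, comment="#")
    reps = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return DoseResponse(ratios=df["ratio"].to_numpy(),
                        percent_reduced=df["percent_reduced"].to_numpy(),
                        replicate_ids=reps)


def load_timecourse(path, substrate_initial: float,
                    surrogate_extinction: dict[str, float] | None = None,
                    area_scale: float = 1.0) -> TimeCourse:
    """Read a time course from CSV columns time_min,product,conc_uM (or
    time_min,product,area plus a per-product surrogate extinction table used
    to convert peak areas: conc = area * area_scale / epsilon)."""
    df = pd.read_csv(path, comment="#")
    if "conc_uM" not in df.columns:
        if surrogate_extinction is None:
            raise ValueError("area data requires a surrogate extinction table")
        df["conc_uM"] = [row.area * area_scale / surrogate_extinction[row.product]
                         for row in df.itertuples()]
    wide = df.pivot_table(index="time_min", columns="product", values="conc_uM")
    return TimeCourse(times=wide.index.to_numpy(),
                      concentrations={str(c): wide[c].to_numpy() for c in wide.columns},
                      substrate_initial=substrate_initial)


def dose_response_from_traces(traces: list[KineticTrace], t_end: float = 30.0) -> DoseResponse:
    """Build the dose-response table by applying %DPPHred to each trace."""
    ratios = [tr.antioxidant_ratio for tr in traces]
    reds = [percent_dpph_reduced(tr, t_end) for tr in traces]
    reps = [tr.replicate_id for tr in traces]
    return DoseResponse(ratios=np.array(ratios), percent_reduced=np.array(reds),
                        replicate_ids=np.array(reps))
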