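"""Rate estimation from time courses.

Covers the kinetic readouts of the pipeline: exponential cell growth rates,
per-cell exometabolomic uptake/secretion fluxes and their fold/stoichiometry
summaries, terminal drug half-lives from tissue concentration decays,
initial-rate estimation from substrate-oxidation plate kinetics with grouped
Welch/Benjamini-Hochberg testing, and xenograft tumor-volume summaries.

Unit conventions: medium amounts in micromoles, cell-specific fluxes in
fmol per cell per hour, growth rates in 1/h, pharmacokinetic times in minutes
and concentrations in micromolar, plate absorbance in AU with time in minutes,
tumor dimensions in mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TimeCourse",
    "FluxEstimate",
    "GrowthFit",
    "PKFit",
    "InitialRate",
    "FluxComparison",
    "bh_adjust",
    "welch_t",
    "fit_growth",
    "exoflux",
    "flux_fold_and_stoichiometry",
    "pk_fit",
    "biolog_initial_rate",
    "biolog_compare",
    "tumor_volume",
    "endpoint_test",
]

#: Conversion from (fmol/cell/h * cells * h) to micromoles.
FMOL_TO_UMOL = 1e-9

#: Welch statistic reported when both groups have zero variance but differ.
ZERO_VARIANCE_T_CAP = 1e6

TIMECOURSE_KINDS = (
    "medium_amount",
    "cell_count",
    "concentration",
    "absorbance590",
    "absorbance750",
    "tumor_volume",
)


@dataclass
class TimeCourse:
    """Replicated time series of one measured quantity.

    ``data`` holds columns ``time``, ``value``, ``replicate``; ``kind``
    declares what is measured (and thereby its units); ``meta`` carries
    provenance such as the generating scenario, condition, and seed.
    """

    series_id: str
    kind: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TIMECOURSE_KINDS:
            raise ValueError(f"unknown time-course kind {self.kind!r}")
        required = {"time", "value", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"time course needs columns {sorted(required)}")
        if (self.data["time"] < 0).any():
            raise ValueError("times must be non-negative")
        self.data = self.data.sort_values(
            ["replicate", "time"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    def replicate_values(self, time: float) -> np.ndarray:
        sel = self.data[np.isclose(self.data["time"], time)]
        return sel.sort_values("replicate")["value"].to_numpy()

    def to_rows(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "series_id", self.series_id)
        out.insert(1, "kind", self.kind)
        return out


def _require_fittable(tc: TimeCourse, min_times: int = 3) -> None:
    if len(tc.times) < min_times:
        raise ValueError(
            f"{tc.series_id}: need >= {min_times} distinct times for a fit"
        )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Welch's unequal-variance two-sided t-test with degenerate-input guards.

    Returns (t, p, note). Zero-variance groups make the standard statistic
    undefined: identical constant groups are reported as t=0, p=1; constant
    but different groups get a capped statistic and p ~ 0 with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0, "identical zero-variance groups"
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return sign * ZERO_VARIANCE_T_CAP, 0.0, "zero-variance groups; statistic capped"
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), ""


# ---------------------------------------------------------------------------
# growth and exometabolomic flux
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFit:
    mu: float           # 1/h
    se: float
    n0_fit: float       # intercept-implied initial count
    r_squared: float


def fit_growth(counts: TimeCourse) -> GrowthFit:
    """Exponential growth rate: least-squares slope of ln(count) vs time."""
    _require_fittable(counts)
    values = counts.data["value"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("cell counts must be positive")
    t = counts.data["time"].to_numpy(dtype=float)
    res = stats.linregress(t, np.log(values))
    return GrowthFit(mu=float(res.slope), se=float(res.stderr),
                     n0_fit=float(np.exp(res.intercept)),
                     r_squared=float(res.rvalue**2))


@dataclass(frozen=True)
class FluxEstimate:
    """Per-cell exchange flux in fmol/cell/h.

    ``J`` is positive in the declared direction (consumption or secretion);
    ``direction_warning`` is set when the medium change runs opposite to the
    declared direction.
    """

    J: float
    se: float
    mu_used: float
    method: str
    direction: str
    direction_warning: bool = False


def _growth_integral(mu: float, t: np.ndarray) -> np.ndarray:
    """Integral of N(t)/N0 = e^{mu t} from 0 to t, in hours."""
    t = np.asarray(t, dtype=float)
    if mu < 1e-6:
        return t
    return (np.exp(mu * t) - 1.0) / mu


def exoflux(
    medium: TimeCourse,
    mu: float,
    n0: float,
    direction: str,
    method: str = "endpoint",
) -> FluxEstimate:
    """Per-cell uptake/secretion flux from a medium-amount time course.

    Under exponential growth N(t) = N0 e^{mu t} and constant per-cell flux J,
    the medium amount follows M(t) = M0 -/+ J N0 (e^{mu t} - 1)/mu (minus for
    consumption). The default endpoint method inverts this from the first-
    to-last amount difference per replicate; ``method="regression"`` instead
    regresses M(t) on the growth integral across all timepoints.
    """
    if mu < 0:
        raise ValueError("negative growth rates are not supported")
    if direction not in ("consumption", "secretion"):
        raise ValueError("direction must be 'consumption' or 'secretion'")
    if method not in ("endpoint", "regression"):
        raise ValueError("method must be 'endpoint' or 'regression'")
    _require_fittable(medium, min_times=2)

    sign = -1.0 if direction == "consumption" else 1.0
    per_rep = []
    for _, grp in medium.data.groupby("replicate"):
        t = grp["time"].to_numpy(dtype=float)
        m = grp["value"].to_numpy(dtype=float)
        g = _growth_integral(mu, t) * n0 * FMOL_TO_UMOL  # umol per (fmol/cell/h)
        if method == "endpoint":
            dg = g[-1] - g[0]
            if dg <= 0:
                raise ValueError("endpoint method needs a positive time span")
            per_rep.append((m[-1] - m[0]) / dg / sign)
        else:
            res = stats.linregress(g, m)
            per_rep.append(res.slope / sign)
    per_rep = np.asarray(per_rep)
    J = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(per_rep.size)) if per_rep.size > 1 else float("nan")
    warn = J < 0
    if warn:
        warnings.warn(
            f"{medium.series_id}: medium change opposite to declared "
            f"{direction}; flux reported with negative sign",
            stacklevel=2,
        )
    return FluxEstimate(J=J, se=se, mu_used=mu, method=method,
                        direction=direction, direction_warning=warn)


@dataclass(frozen=True)
class FluxComparison:
    fold_glc: float
    fold_lac: float
    delta_ratio: float | None
    suppressed_reason: str | None = None


def flux_fold_and_stoichiometry(
    glc_treated: FluxEstimate,
    glc_control: FluxEstimate,
    lac_treated: FluxEstimate,
    lac_control: FluxEstimate,
) -> FluxComparison:
    """Treated/control flux folds and excess-lactate : excess-glucose ratio.

    A ratio of 2 mol lactate per mol excess glucose means the extra glucose
    uptake is fully diverted to fermentation. The ratio is suppressed when the
    excess glucose flux is not resolved from zero (|dJ_glc| < 3 se).
    """
    fold_glc = glc_treated.J / glc_control.J
    fold_lac = lac_treated.J / lac_control.J
    d_glc = glc_treated.J - glc_control.J
    d_lac = lac_treated.J - lac_control.J
    se_d = math.hypot(
        0.0 if math.isnan(glc_treated.se) else glc_treated.se,
        0.0 if math.isnan(glc_control.se) else glc_control.se,
    )
    if abs(d_glc) < 3 * se_d or d_glc == 0:
        return FluxComparison(fold_glc, fold_lac, None,
                              "excess glucose flux not resolved from zero")
    return FluxComparison(fold_glc, fold_lac, d_lac / d_glc)


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKFit:
    k: float | None          # elimination constant, 1/min
    t_half: float | None     # min
    c_first: float           # fitted concentration at the first sampled time
    r_squared: float
    message: str = ""


def pk_fit(conc: TimeCourse) -> PKFit:
    """Mono-exponential elimination fit: least squares on ln C vs t.

    Models only the terminal decay from the first sampled time onward; no
    absorption phase. A non-negative slope is reported as "no measurable
    elimination" rather than a negative half-life.
    """
    _require_fittable(conc)
    values = conc.data["value"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("concentrations must be positive")
    t = conc.data["time"].to_numpy(dtype=float)
    res = stats.linregress(t, np.log(values))
    t0 = float(t.min())
    c_first = float(np.exp(res.intercept + res.slope * t0))
    if res.slope >= 0:
        return PKFit(k=None, t_half=None, c_first=c_first,
                     r_squared=float(res.rvalue**2),
                     message="no measurable elimination")
    k = -float(res.slope)
    return PKFit(k=k, t_half=math.log(2) / k, c_first=c_first,
                 r_squared=float(res.rvalue**2))


# ---------------------------------------------------------------------------
# substrate-oxidation plate kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialRate:
    rate: float            # AU/min
    window_points: int
    r_squared: float
    quality_flag: bool     # True when no prefix window met the R^2 gate


MIN_WINDOW = 4
MAX_WINDOW = 12
WINDOW_R2 = 0.98


def _prefix_r2_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(res.slope), r2


def biolog_initial_rate(a590: TimeCourse, a750: TimeCourse) -> InitialRate:
    """Initial reaction rate from background-corrected dye-reduction kinetics.

    The long-wavelength channel is a shared measurement baseline and is
    subtracted point-by-point. The "initial linear part" is formalized as the
    longest prefix of 4-12 points whose linear fit has R^2 >= 0.98 (ties go to
    more points); the rate is that window's slope. If no prefix qualifies the
    first 4 points are used and the result is quality-flagged.
    """
    sig = a590.data.merge(
        a750.data, on=["time", "replicate"], suffixes=("_590", "_750")
    )
    if len(sig) != len(a590.data) or len(sig) != len(a750.data):
        raise ValueError("absorbance channels are not time-aligned")
    rates, windows, r2s, flags = [], [], [], []
    for _, grp in sig.groupby("replicate"):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        y = (grp["value_590"] - grp["value_750"]).to_numpy(dtype=float)
        if t.size < MIN_WINDOW:
            raise ValueError("need >= 4 points per replicate")
        best = None
        for npts in range(MIN_WINDOW, min(MAX_WINDOW, t.size) + 1):
            slope, r2 = _prefix_r2_slope(t[:npts], y[:npts])
            if r2 >= WINDOW_R2:
                best = (slope, npts, r2)  # ties broken toward more points
        if best is None:
            slope, r2 = _prefix_r2_slope(t[:MIN_WINDOW], y[:MIN_WINDOW])
            best = (slope, MIN_WINDOW, r2)
            flags.append(True)
        else:
            flags.append(False)
        rates.append(best[0])
        windows.append(best[1])
        r2s.append(best[2])
    return InitialRate(rate=float(np.mean(rates)),
                       window_points=int(np.median(windows)),
                       r_squared=float(np.mean(r2s)),
                       quality_flag=any(flags))


def biolog_compare(rates: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    """Per-substrate drug-vs-control rate comparison with BH FDR control.

    ``rates`` is long-format with columns (substrate, group, replicate, rate);
    groups are compared against ``control`` with Welch's t-test and q-values
    are BH-adjusted across the substrates of each drug (the plate). Log2 rate
    ratios are suppressed (NaN) when the control rate is not positive; the
    difference is still tested.
    """
    required = {"substrate", "group", "replicate", "rate"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rates table needs columns {sorted(required)}")
    out = []
    groups = [g for g in rates["group"].unique() if g != control]
    for drug in groups:
        rows = []
        for substrate, sub in rates.groupby("substrate"):
            ctrl = sub.loc[sub["group"] == control, "rate"].to_numpy()
            trt = sub.loc[sub["group"] == drug, "rate"].to_numpy()
            if ctrl.size < 3 or trt.size < 3:
                raise ValueError(
                    f"{substrate}: need >= 3 replicates per group"
                )
            t, p, note = welch_t(trt, ctrl)
            ctrl_mean = ctrl.mean()
            ratio = (
                math.log2(trt.mean() / ctrl_mean)
                if ctrl_mean > 0 and trt.mean() > 0 else float("nan")
            )
            rows.append((substrate, drug, ratio, t, p, note))
        df = pd.DataFrame(
            rows, columns=["substrate", "group", "log2_ratio", "t", "p", "note"]
        )
        df["q"] = bh_adjust(df["p"].to_numpy())
        out.append(df)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["substrate", "group", "log2_ratio", "t", "p", "note", "q"]
    )


# ---------------------------------------------------------------------------
# in-vivo summaries
# ---------------------------------------------------------------------------

def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume, 0.5 * L * W^2 (mm^3), with L >= W enforced."""
    if length <= 0 or width <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width > length:
        warnings.warn("width exceeds length; dimensions swapped", stacklevel=2)
        length, width = width, length
    return 0.5 * length * width**2


def endpoint_test(volumes_treated: Sequence[float],
                  volumes_control: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test on final-timepoint tumor volumes."""
    trt = np.asarray(volumes_treated, dtype=float)
    ctrl = np.asarray(volumes_control, dtype=float)
    if trt.size < 3 or ctrl.size < 3:
        raise ValueError("need >= 3 animals per arm")
    t, p, _ = welch_t(trt, ctrl)
    return t, p
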