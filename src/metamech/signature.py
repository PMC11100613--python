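"""Differential metabolomics and mechanism calling.

Turns replicated peak-intensity tables into per-drug response profiles
(log2 fold-changes with Welch tests and Benjamini-Hochberg q-values), tests
dose trends, classifies the mechanism of action from a small marker panel
(FASN-inhibition signature vs a Complex-I-like pattern), and compares and
clusters whole response profiles by Pearson correlation.

The FASN-inhibition signature is a dose-dependent intracellular accumulation
of malonate, succinate, and their CoA conjugates: malonyl-CoA piles up behind
the blocked synthase, its hydrolysis releases free malonate, and malonate in
turn inhibits succinate dehydrogenase, backing up succinate and succinyl-CoA.
A Complex I block produces nearly the opposite pattern: the NADH/NAD+ ratio,
glycerol 3-phosphate, and lactate rise while TCA-cycle pools are depleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from .kinetics import bh_adjust, welch_t

__all__ = [
    "ResponseProfile",
    "TrendResult",
    "MechanismCall",
    "FASN_SIGNATURE",
    "COMPLEX_I_UP",
    "COMPLEX_I_DOWN",
    "fold_changes",
    "dose_trend",
    "classify_mechanism",
    "profile_correlation",
    "cluster_profiles",
    "mutual_nearest_neighbors",
]

#: Minimal marker set whose joint dose-dependent accumulation calls FASN
#: inhibition, with default top-dose fold thresholds. Thresholds sit roughly
#: an order of magnitude below typically observed effects, for robustness.
FASN_SIGNATURE = {
    "malonate": 10.0,
    "succinate": 2.0,
    "malonyl_coa": 2.0,
    "succinyl_coa": 1.2,
}

#: Markers expected to rise under Complex I inhibition (redox overflow).
COMPLEX_I_UP = ("nadh_nad_ratio", "glycerol_3_phosphate", "lactate", "pyruvate")
#: Markers expected to fall (TCA-cycle pool depletion and linked CoA esters).
COMPLEX_I_DOWN = (
    "succinate", "succinyl_coa", "malonyl_coa", "acetyl_coa",
    "citrate", "alpha_ketoglutarate", "fumarate", "malate", "aspartate",
)

#: Mean expected-direction log2 effect over the Complex I markers required
#: for a complex_i_like call (~1.4-fold average move in the expected sense).
COMPLEX_I_SCORE_THRESHOLD = 0.5

#: A Complex I call additionally requires no malonate accumulation.
COMPLEX_I_MALONATE_CEILING = 2.0

Q_THRESHOLD = 0.05


@dataclass
class ResponseProfile:
    """Per-drug/dose response vector across a shared feature set."""

    drug: str
    dose: float
    features: list[str]
    log2fc: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        n = len(self.features)
        if not (self.log2fc.size == self.p.size == self.q.size == n):
            raise ValueError("profile vectors must align with features")
        finite_q = self.q[np.isfinite(self.q)]
        if finite_q.size and (finite_q.min() < 0 or finite_q.max() > 1 + 1e-12):
            raise ValueError("q-values must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def fold(self, metabolite: str) -> float:
        return float(2.0 ** self.log2fc[self.features.index(metabolite)])

    def q_of(self, metabolite: str) -> float:
        return float(self.q[self.features.index(metabolite)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metabolite": self.features,
            "drug": self.drug,
            "dose": self.dose,
            "log2fc": self.log2fc,
            "p": self.p,
            "q": self.q,
            "significant": self.q < Q_THRESHOLD,
        })


def _control_mask(table: pd.DataFrame) -> pd.Series:
    return (table["drug"] == "vehicle") | (table["dose"] == 0)


def fold_changes(
    table: pd.DataFrame,
    drug: str,
    dose: float,
    compartment: str | None = None,
) -> ResponseProfile:
    """Per-metabolite log2 fold-change profile against the vehicle group.

    Fold-changes are ratios of geometric means (treated over control), the
    test is Welch's unequal-variance t on natural-log intensities, and
    q-values are BH-adjusted across all metabolites in the profile.
    Non-positive intensities are floored at half the smallest positive
    intensity in the table (a detection-limit convention); the count of
    floored values is recorded on the profile.
    """
    required = {"metabolite", "drug", "dose", "replicate", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    work = table.copy()
    if compartment is not None and "compartment" in work.columns:
        work = work[work["compartment"] == compartment]

    positive = work.loc[work["intensity"] > 0, "intensity"]
    if positive.empty:
        raise ValueError("peak table has no positive intensities")
    floor = 0.5 * float(positive.min())
    n_floored = int((work["intensity"] <= 0).sum())
    work.loc[work["intensity"] <= 0, "intensity"] = floor

    ctrl = work[_control_mask(work)]
    trt = work[(work["drug"] == drug) & np.isclose(work["dose"], dose)]
    if trt.empty:
        raise ValueError(f"no rows for drug={drug!r} at dose={dose!r}")

    feats, l2fc, pvals = [], [], []
    for metabolite, trt_grp in trt.groupby("metabolite", sort=True):
        ctrl_vals = ctrl.loc[ctrl["metabolite"] == metabolite, "intensity"]
        if len(trt_grp) < 2 or len(ctrl_vals) < 2:
            raise ValueError(
                f"{metabolite}: need >= 2 replicates in each group"
            )
        log_t = np.log(trt_grp["intensity"].to_numpy(dtype=float))
        log_c = np.log(ctrl_vals.to_numpy(dtype=float))
        _, p, _ = welch_t(log_t, log_c)
        feats.append(metabolite)
        l2fc.append((log_t.mean() - log_c.mean()) / math.log(2))
        pvals.append(p)

    q = bh_adjust(np.asarray(pvals))
    return ResponseProfile(drug=drug, dose=float(dose), features=feats,
                           log2fc=np.asarray(l2fc), p=np.asarray(pvals),
                           q=q, n_floored=n_floored)


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p: float
    direction: int  # sign of rho; 0 when no trend is defined


def dose_trend(table: pd.DataFrame, drug: str, metabolite: str) -> TrendResult:
    """Spearman rank correlation of dose vs replicate-level log-intensity.

    The vehicle group enters at dose 0. Constant intensities leave the rank
    correlation undefined; that is reported as no trend (direction 0) rather
    than NaN-propagated.
    """
    rows = table[
        (table["metabolite"] == metabolite)
        & ((table["drug"] == drug) | _control_mask(table))
    ]
    if rows["dose"].nunique() < 3:
        raise ValueError("dose trend needs >= 3 dose levels incl. vehicle")
    intensities = rows["intensity"].to_numpy(dtype=float)
    if np.ptp(intensities) == 0:
        return TrendResult(rho=float("nan"), p=1.0, direction=0)
    rho, p = stats.spearmanr(rows["dose"].to_numpy(dtype=float),
                             np.log(intensities))
    if not np.isfinite(rho):
        return TrendResult(rho=float("nan"), p=1.0, direction=0)
    return TrendResult(rho=float(rho), p=float(p), direction=int(np.sign(rho)))


@dataclass
class MechanismCall:
    label: str  # fasn_inhibition | complex_i_like | indeterminate
    fasn_score: float
    complex_i_score: float
    evidence: pd.DataFrame = field(repr=False)
    missing_markers: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


def classify_mechanism(
    profiles: list[ResponseProfile],
    trends: dict[str, TrendResult],
    fasn_thresholds: dict[str, float] | None = None,
    complex_i_score_threshold: float = COMPLEX_I_SCORE_THRESHOLD,
) -> MechanismCall:
    """Call the mechanism of action from dose-resolved response profiles.

    A ``fasn_inhibition`` call requires, for every signature metabolite, a
    top-dose fold above its threshold with q < 0.05 and a positive dose
    trend. A ``complex_i_like`` call requires the mean expected-direction
    log2 effect over the Complex I marker panel to exceed the score threshold
    while malonate stays below a 2-fold ceiling. Anything else (including a
    profile missing signature markers) is ``indeterminate``. Both scores are
    always reported alongside the call.
    """
    if not profiles:
        raise ValueError("need at least one response profile")
    fasn_thresholds = dict(fasn_thresholds or FASN_SIGNATURE)
    top = max(profiles, key=lambda pr: pr.dose)

    missing = [m for m in fasn_thresholds if m not in top.features]
    records = []

    fasn_effects = []
    fasn_ok = not missing
    for met, fold_min in fasn_thresholds.items():
        if met in missing:
            records.append((met, "fasn", np.nan, np.nan, np.nan, False))
            continue
        fold = top.fold(met)
        qv = top.q_of(met)
        trend = trends.get(met)
        direction = trend.direction if trend is not None else 0
        passed = fold >= fold_min and qv < Q_THRESHOLD and direction > 0
        fasn_ok &= passed
        fasn_effects.append(math.log2(fold))
        records.append((met, "fasn", fold, qv, float(direction), passed))
    fasn_score = float(np.mean(fasn_effects)) if fasn_effects else float("nan")

    signed = []
    for met, sign in [(m, +1) for m in COMPLEX_I_UP] + [(m, -1) for m in COMPLEX_I_DOWN]:
        if met not in top.features:
            continue
        effect = sign * math.log2(top.fold(met))
        signed.append(effect)
        records.append((met, "complex_i", top.fold(met), top.q_of(met),
                        float(sign), effect > 0))
    complex_i_score = float(np.mean(signed)) if signed else float("nan")

    malonate_fold = top.fold("malonate") if "malonate" in top.features else float("nan")
    complex_ok = (
        len(signed) >= 4
        and complex_i_score > complex_i_score_threshold
        and (math.isnan(malonate_fold) or malonate_fold < COMPLEX_I_MALONATE_CEILING)
    )

    if missing:
        label = "indeterminate"
    elif fasn_ok:
        label = "fasn_inhibition"
    elif complex_ok:
        label = "complex_i_like"
    else:
        label = "indeterminate"

    evidence = pd.DataFrame(
        records,
        columns=["metabolite", "panel", "fold", "q", "direction", "passed"],
    )
    return MechanismCall(
        label=label,
        fasn_score=fasn_score,
        complex_i_score=complex_i_score,
        evidence=evidence,
        missing_markers=missing,
        thresholds={
            "fasn_folds": fasn_thresholds,
            "q": Q_THRESHOLD,
            "complex_i_score": complex_i_score_threshold,
            "complex_i_malonate_ceiling": COMPLEX_I_MALONATE_CEILING,
        },
    )


def profile_correlation(
    a: ResponseProfile, b: ResponseProfile
) -> tuple[float, float, int]:
    """Pearson correlation of two log2 fold-change profiles.

    Computed over the intersection of features with finite values in both
    profiles (no imputation); p is the two-sided t-distribution p-value.
    """
    shared = [f for f in a.features if f in set(b.features)]
    xa = np.array([a.log2fc[a.features.index(f)] for f in shared])
    xb = np.array([b.log2fc[b.features.index(f)] for f in shared])
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < 10:
        raise ValueError("need >= 10 shared finite features")
    r, p = stats.pearsonr(xa[ok], xb[ok])
    return float(r), float(p), int(ok.sum())


def _correlation_distance(profiles: list[ResponseProfile]) -> np.ndarray:
    n = len(profiles)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _, _ = profile_correlation(profiles[i], profiles[j])
            dist[i, j] = dist[j, i] = 1.0 - r
    return dist


def cluster_profiles(
    profiles: list[ResponseProfile], n_clusters: int | None = None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on 1 - Pearson r distance.

    Profiles are ordered by (drug, dose) label before clustering so that ties
    resolve deterministically. Returns (linkage matrix, ordered labels, flat
    cluster assignment); identical profiles simply merge at height 0.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles to cluster")
    order = sorted(range(len(profiles)),
                   key=lambda i: (profiles[i].drug, profiles[i].dose))
    profiles = [profiles[i] for i in order]
    labels = [f"{p.drug}@{p.dose:g}" for p in profiles]
    dist = np.clip(_correlation_distance(profiles), 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False),
                                method="average")
    if n_clusters is None:
        n_clusters = max(2, int(round(math.sqrt(len(profiles)))))
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, labels, flat


def mutual_nearest_neighbors(
    profiles: list[ResponseProfile], label_a: str, label_b: str
) -> bool:
    """True when the two named drugs are each other's nearest profile."""
    labels = [p.drug for p in profiles]
    dist = _correlation_distance(profiles)
    np.fill_diagonal(dist, np.inf)
    ia, ib = labels.index(label_a), labels.index(label_b)
    return bool(np.argmin(dist[ia]) == ib and np.argmin(dist[ib]) == ia)
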