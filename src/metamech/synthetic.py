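"""Scenario-based synthetic data generator.

Every input the pipeline consumes can be generated here under a named
mechanism scenario with the ground truth recorded, so that each downstream
stage (isotope correction, tracing inference, differential signatures,
kinetics) is testable end-to-end without external data.

Scenarios encode the study conditions of a drug-profiling experiment on
cultured breast-cancer cells: a FASN-inhibitor scenario (massive malonate and
succinate accumulation with malonyl-/succinyl-CoA), a Complex-I-inhibition
scenario (reductive stress: NADH/NAD+, glycerol 3-phosphate and lactate up,
TCA pools down), a 24-h glycolytic-switch scenario with a 9-fold glucose and
18-fold lactate flux increase obeying 1:2 glucose-to-lactate stoichiometry,
a four-tissue mouse pharmacokinetics scenario, a zebrafish whole-embryo
lactate scenario, and a substrate-oxidation plate scenario.

Statistical structure emulated: multiplicative log-normal intensity noise
(mean-preserving), Hill-type dose responses, natural-abundance-convolved
isotopologue spectra, exponential growth/decay. Raw spectra, chromatography,
and matrix effects are out of scope.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .isotopes import as_mid, naturalize_mid, NATURAL_ABUNDANCE, convolve_mids
from .kinetics import TimeCourse, FMOL_TO_UMOL
from .signature import ResponseProfile

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioConfig",
    "GeneratedStudy",
    "make_scenario",
    "feature_panel",
    "generate_peak_table",
    "generate_zebrafish_table",
    "generate_isotopologue_spectrum",
    "generate_tracer_panel",
    "generate_profile_pair",
    "generate_profile_panel",
    "generate_medium_timecourse",
    "generate_pk_timecourse",
    "generate_plate_trace",
    "generate_biolog_plate",
    "generate_study",
]

SCENARIO_NAMES = (
    "vehicle",
    "fasn_inhibitor",
    "complex_i",
    "rotenone_like",
    "fasnall_24h",
    "pk_mouse",
    "zebrafish",
    "biolog",
)

#: Default dose grid (uM), roughly half-log spaced; the Hill midpoint sits at
#: the second dose so the top dose realizes ~99% of the scenario's true fold.
DEFAULT_DOSES = (0.1, 0.3, 1.0, 3.0)

#: Correlation between the log2 fold-change profiles of two drugs sharing a
#: mechanism signature; E[Pearson r] = sigma_s^2 / (sigma_s^2 + sigma_eps^2).
DEFAULT_PROFILE_RHO = 0.56

#: Log-normal CV of replicate cell counts.
COUNT_CV = 0.05

_COMPLEX_I_FOLDS = {
    "succinate": 0.5,
    "succinyl_coa": 0.5,
    "malonyl_coa": 0.4,
    "acetyl_coa": 0.6,
    "nadh_nad_ratio": 3.0,
    "glycerol_3_phosphate": 5.0,
    "lactate": 3.0,
    "pyruvate": 2.0,
    "citrate": 0.4,
    "alpha_ketoglutarate": 0.5,
    "malate": 0.35,
    "fumarate": 0.45,
    "aspartate": 0.5,
    "malonate": 1.0,
}

_CORE_METABOLITES = (
    "malonate", "succinate", "malonyl_coa", "succinyl_coa", "acetyl_coa",
    "nadh_nad_ratio", "glycerol_3_phosphate", "lactate", "pyruvate",
    "citrate", "alpha_ketoglutarate", "fumarate", "malate", "aspartate",
)

#: Per-tissue (concentration at 15 min, uM; terminal half-life, min).
_PK_MOUSE = {
    "liver": (9.2, 48.0),
    "heart": (3.75, 85.0),
    "brain": (3.75, 85.0),
    "plasma": (0.8, 88.0),
}

_BIOLOG_SUBSTRATES = (
    "malate", "fumarate", "hydroxybutyrate", "succinate", "pyruvate",
    "glutamate", "glutamine", "citrate", "alpha_ketoglutarate",
    "isocitrate", "lactate", "glycerol_phosphate",
)


@dataclass
class ScenarioConfig:
    """Ground truth for one simulated experiment.

    ``true_fold`` maps metabolite to its fold-change at saturating dose;
    ``fluxes`` maps condition to (J_glc, J_lac) in fmol/cell/h and
    ``growth_rate`` to mu in 1/h; ``pk`` maps tissue to (C at 15 min in uM,
    half-life in min). ``mechanism`` tags scenarios that share a latent
    response signature for profile-pair generation.
    """

    name: str
    mechanism: str | None = None
    true_fold: dict = field(default_factory=dict)
    ec50_index: int = 1
    hill: float = 2.0
    intensity_cv: float = 0.20
    n_features: int = 208
    shared_signature_sd: float = 1.0
    profile_noise_sd: float = math.sqrt((1 - DEFAULT_PROFILE_RHO) / DEFAULT_PROFILE_RHO)
    fluxes: dict = field(default_factory=dict)
    growth_rate: dict = field(default_factory=dict)
    n0_cells: float = 1e6
    medium_m0: dict = field(default_factory=dict)
    pk: dict = field(default_factory=dict)
    pool_folds: dict = field(default_factory=dict)
    tracing: dict = field(default_factory=dict)
    biolog: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for met, fold in self.true_fold.items():
            if fold <= 0:
                raise ValueError(f"fold for {met} must be strictly positive")
        if not 0 < self.intensity_cv < 1:
            raise ValueError("intensity_cv must lie in (0, 1)")
        if self.hill <= 0:
            raise ValueError("hill coefficient must be positive")
        for cond, mu in self.growth_rate.items():
            if mu < 0:
                raise ValueError(f"growth rate for {cond} must be >= 0")
        for tissue, (c_ref, _) in self.pk.items():
            if c_ref <= 0:
                raise ValueError(f"PK concentration for {tissue} must be positive")
        if self.name == "fasnall_24h" and self.fluxes:
            (jg_c, jl_c) = self.fluxes["control"]
            (jg_t, jl_t) = self.fluxes["treated"]
            if not math.isclose(jl_t - jl_c, 2.0 * (jg_t - jg_c),
                                rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    "fasnall_24h fluxes must satisfy the 1:2 glucose-to-"
                    "lactate carbon balance dJ_lac = 2 dJ_glc"
                )

    def rng(self, *labels: str) -> np.random.Generator:
        """Deterministic per-table generator: master seed + stable label hash."""
        key = zlib.crc32("/".join((self.name,) + labels).encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def reseeded(self, seed: int | None) -> "ScenarioConfig":
        if seed is None or seed == self.seed:
            return self
        return ScenarioConfig(**{**asdict(self), "seed": seed})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneratedStudy:
    """Bundle of all tables one scenario produces, with the truth echoed."""

    peak_table: pd.DataFrame | None
    isotopologue_tables: pd.DataFrame | None
    medium_timecourses: list[TimeCourse]
    pk_timecourses: list[TimeCourse]
    plate_traces: list[TimeCourse]
    truth: ScenarioConfig


def make_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Build a fully populated scenario configuration by name."""
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIO_NAMES)}"
        )
    cfg = ScenarioConfig(name=name, seed=seed)
    if name == "vehicle":
        cfg.mechanism = "null"
        cfg.true_fold = {m: 1.0 for m in _CORE_METABOLITES}
    elif name == "fasn_inhibitor":
        cfg.mechanism = "fasn"
        cfg.true_fold = {m: 1.0 for m in _CORE_METABOLITES}
        cfg.true_fold.update({
            "malonate": 1000.0,
            "succinate": 10.0,
            "malonyl_coa": 20.0,
            "succinyl_coa": 2.0,
            "acetyl_coa": 1.75,
        })
    elif name in ("complex_i", "rotenone_like", "fasnall_24h"):
        cfg.mechanism = "complex_i"
        cfg.true_fold = {m: 1.0 for m in _CORE_METABOLITES}
        cfg.true_fold.update(_COMPLEX_I_FOLDS)
        if name == "fasnall_24h":
            # Baselines chosen so the treated condition shows a 9-fold glucose
            # and 18-fold lactate flux increase while the excess obeys the 1:2
            # carbon balance: J_lac,ctrl = 0.941 J_glc,ctrl.
            cfg.fluxes = {"control": (100.0, 94.1), "treated": (900.0, 1694.1)}
            cfg.growth_rate = {"control": math.log(2) / 30.0,
                               "treated": math.log(2) / 60.0}
            cfg.medium_m0 = {"glucose": 50.0, "lactate": 0.0}  # umol per dish
        cfg.tracing = {
            "anaplerosis_share": 0.6,
            "reductive_share": 0.5,
            "acetyl_glc": (0.70, 0.05, 0.25),
            "malate_labeled": 0.5,
        }
    elif name == "pk_mouse":
        cfg.pk = dict(_PK_MOUSE)
    elif name == "zebrafish":
        cfg.intensity_cv = 0.25
        cfg.pool_folds = {"rotenone": 15.0, "fasnall": 4.0}
    elif name == "biolog":
        cfg.biolog = {
            "substrates": list(_BIOLOG_SUBSTRATES),
            "control_rate": 0.02,      # AU/min
            "plateau": 1.0,            # AU
            "rate_cv": 0.10,
            "absorbance_sd": 0.002,    # AU, per-point
            "inhibited": {"malate": 0.2, "fumarate": 0.2, "hydroxybutyrate": 0.2},
        }
    if name in ("vehicle", "fasn_inhibitor"):
        cfg.tracing = {
            "anaplerosis_share": 0.2,
            "reductive_share": 0.15,
            "acetyl_glc": (0.45, 0.05, 0.50),
            "malate_labeled": 0.5,
        }
    return cfg


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def feature_panel(n_features: int) -> pd.DataFrame:
    """Profiled feature set: named markers plus unaffected filler features.

    The first half of the panel is intracellular, the rest medium, mirroring
    the paired cell-extract / spent-medium design of profiling experiments.
    """
    if n_features < len(_CORE_METABOLITES):
        raise ValueError("n_features smaller than the marker panel")
    names = list(_CORE_METABOLITES)
    names += [f"met_{i:03d}" for i in range(n_features - len(names))]
    half = max(len(_CORE_METABOLITES), n_features // 2)
    compartments = ["intracellular"] * half + ["medium"] * (n_features - half)
    return pd.DataFrame({"metabolite": names, "compartment": compartments})


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative log-normal noise factor."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))


def _hill_effect(fold: float, dose: float, ec50: float, h: float) -> float:
    occupancy = dose**h / (dose**h + ec50**h)
    return 1.0 + (fold - 1.0) * occupancy


def generate_peak_table(
    cfg: ScenarioConfig,
    doses=DEFAULT_DOSES,
    n_reps: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a long-format peak-intensity table for one drug plus vehicle.

    intensity(met, dose) = baseline * Hill(dose) * exp(eps) with
    eps ~ Normal(-sigma^2/2, sigma^2), sigma^2 = ln(1 + cv^2), so expected
    intensities follow the Hill curve exactly. Vehicle replicates are drawn
    at fold 1 and dose 0. Deterministic for a fixed config and seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (fold estimation needs replication)")
    doses = np.asarray(doses, dtype=float)
    if doses.size < 1 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly ascending")
    if cfg.ec50_index >= doses.size:
        raise ValueError("ec50_index outside the dose grid")

    local = cfg.reseeded(seed)
    rng = local.rng("peaks")
    panel = feature_panel(cfg.n_features)
    ec50 = float(doses[cfg.ec50_index])

    baselines = 10.0 ** rng.uniform(4.0, 7.0, size=len(panel))
    # The dosed arm needs a name distinct from the control group label, even
    # in the null scenario whose "drug" has no effect.
    drug_name = cfg.name if cfg.name != "vehicle" else "null_drug"
    rows = []
    for dose in np.concatenate([[0.0], doses]):
        drug = "vehicle" if dose == 0.0 else drug_name
        for (met, comp), base in zip(
            panel.itertuples(index=False), baselines, strict=True
        ):
            fold = cfg.true_fold.get(met, 1.0)
            effect = 1.0 if dose == 0.0 else _hill_effect(fold, dose, ec50, cfg.hill)
            noise = _lognormal_factor(rng, cfg.intensity_cv, n_reps)
            for rep in range(1, n_reps + 1):
                rows.append((met, comp, drug, dose, rep,
                             base * effect * noise[rep - 1]))
    table = pd.DataFrame(
        rows,
        columns=["metabolite", "compartment", "drug", "dose", "replicate", "intensity"],
    )
    table["scenario"] = cfg.name
    table["seed"] = local.seed
    return table


def generate_zebrafish_table(
    cfg: ScenarioConfig,
    drug: str,
    n_reps: int = 3,
    seed: int | None = None,
    n_null_features: int = 11,
) -> pd.DataFrame:
    """Pooled whole-embryo lactate intensities, vehicle vs drug exposure.

    The drug effect is applied at its full scenario fold (a single saturating
    exposure, no dose grid); unaffected filler metabolites give the BH
    adjustment a realistic feature set.
    """
    if drug not in cfg.pool_folds:
        raise ValueError(
            f"no whole-embryo fold for drug {drug!r}; "
            f"available: {sorted(cfg.pool_folds)}"
        )
    local = cfg.reseeded(seed)
    rng = local.rng("zebrafish", drug)
    mets = ["lactate"] + [f"met_{i:03d}" for i in range(n_null_features)]
    folds = [cfg.pool_folds[drug]] + [1.0] * n_null_features
    baselines = 10.0 ** rng.uniform(4.0, 6.0, size=len(mets))
    rows = []
    for grp, level in (("vehicle", 0.0), (drug, 1.0)):
        for met, fold, base in zip(mets, folds, baselines, strict=True):
            effect = fold if level > 0 else 1.0
            noise = _lognormal_factor(rng, cfg.intensity_cv, n_reps)
            for rep in range(1, n_reps + 1):
                rows.append((met, "whole_embryo", grp, level, rep,
                             base * effect * noise[rep - 1]))
    table = pd.DataFrame(
        rows,
        columns=["metabolite", "compartment", "drug", "dose", "replicate", "intensity"],
    )
    table["scenario"] = cfg.name
    table["seed"] = local.seed
    return table


# ---------------------------------------------------------------------------
# isotopologue spectra
# ---------------------------------------------------------------------------

def generate_isotopologue_spectrum(
    true_mid,
    n_atoms: int,
    p_natural: float,
    cv: float,
    rng: np.random.Generator | None = None,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """Raw mass-shift spectrum: natural-abundance-convolved MID plus noise.

    Performs the forward convolution that natural-abundance correction
    inverts, applies multiplicative measurement noise, and renormalizes to
    sum 1.
    """
    mid = np.asarray(true_mid, dtype=float)
    if np.any(mid < 0):
        raise ValueError("true MID must be non-negative")
    if mid.size != n_atoms + 1:
        raise ValueError("true MID must have length n_atoms + 1")
    mid = as_mid(mid)
    raw = naturalize_mid(mid, p_natural, tracer_purity)
    if cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        raw = raw * _lognormal_factor(rng, cv, raw.size)
    return raw / raw.sum()


def tracer_truth(cfg: ScenarioConfig, tracer: str) -> dict[str, np.ndarray]:
    """Ground-truth MIDs per metabolite for one tracer under this scenario."""
    tr = cfg.tracing
    if not tr:
        raise ValueError(f"scenario {cfg.name!r} defines no tracing truth")
    a = tr["anaplerosis_share"]
    labeled = tr["malate_labeled"]
    if tracer == "U-13C6-glucose":
        malate = np.array([1 - labeled, 0.0, (1 - a) * labeled, a * labeled, 0.0])
        acetyl = np.asarray(tr["acetyl_glc"], dtype=float)
        citrate = convolve_mids(acetyl, malate)
        return {
            "pyruvate": np.array([0.4, 0.0, 0.0, 0.6]),
            "malate": malate,
            "aspartate": malate.copy(),
            "acetyl_coa_acetyl": acetyl,
            "citrate": citrate,
        }
    if tracer == "U-13C5-glutamine":
        r = tr["reductive_share"]
        unlabeled = 0.3
        citrate = np.zeros(7)
        citrate[0] = unlabeled
        citrate[5] = (1 - unlabeled) * r          # reductive route: M+5
        citrate[4] = (1 - unlabeled) * (1 - r)    # oxidative route: M+4
        f3 = 0.25 + 0.3 * r                        # malate M+3 re-entry marker
        malate = np.array([1 - f3 - 0.15, 0.0, 0.15, f3, 0.0])
        akg = np.array([0.35, 0.0, 0.0, 0.0, 0.0, 0.65])
        return {
            "alpha_ketoglutarate": akg,
            "glutamate": akg.copy(),
            "citrate": citrate,
            "malate": malate,
            "aspartate": malate.copy(),
        }
    raise ValueError(f"unknown tracer {tracer!r}")


_N_ATOMS = {
    "pyruvate": 3, "malate": 4, "aspartate": 4, "citrate": 6,
    "alpha_ketoglutarate": 5, "glutamate": 5, "acetyl_coa_acetyl": 2,
}


def generate_tracer_panel(
    cfg: ScenarioConfig,
    tracer: str,
    n_reps: int = 3,
    cv: float = 0.05,
    seed: int | None = None,
    tracer_purity: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Raw isotopologue spectra for one tracer experiment, plus the truth.

    Returns a long-format table (metabolite, tracer, element, n_atoms,
    mass_shift, intensity, replicate) of natural-abundance-convolved, noisy
    spectra, together with the true MIDs used.
    """
    local = cfg.reseeded(seed)
    rng = local.rng("mids", tracer)
    truth = tracer_truth(cfg, tracer)
    p = NATURAL_ABUNDANCE["C"]
    rows = []
    for met, mid in truth.items():
        n = _N_ATOMS[met]
        for rep in range(1, n_reps + 1):
            raw = generate_isotopologue_spectrum(
                mid, n, p, cv, rng, tracer_purity=tracer_purity
            )
            for shift, inten in enumerate(raw):
                rows.append((met, tracer, "C", n, shift, inten, rep))
    table = pd.DataFrame(
        rows,
        columns=["metabolite", "tracer", "element", "n_atoms",
                 "mass_shift", "intensity", "replicate"],
    )
    table["scenario"] = cfg.name
    table["seed"] = local.seed
    return table, truth


# ---------------------------------------------------------------------------
# response-profile pairs and panels
# ---------------------------------------------------------------------------

def _profile(drug: str, log2fc: np.ndarray) -> ResponseProfile:
    n = log2fc.size
    feats = [f"feat_{i:03d}" for i in range(n)]
    ones = np.ones(n)
    return ResponseProfile(drug=drug, dose=1.0, features=feats,
                           log2fc=log2fc, p=ones, q=ones)


def generate_profile_pair(
    cfg_a: ScenarioConfig,
    cfg_b: ScenarioConfig,
    n_features: int = 208,
    seed: int = 0,
) -> tuple[ResponseProfile, ResponseProfile]:
    """Two drug response profiles, correlated when mechanisms are shared.

    For a shared mechanism, both log2 fold-change vectors are x = s + eps with
    a common latent signature s ~ N(0, sigma_s^2) and independent feature
    noise eps ~ N(0, sigma_eps^2); with the default sigma_eps =
    sigma_s sqrt((1-rho)/rho), rho = 0.56, the expected Pearson correlation
    is 0.56. Unrelated mechanisms get independent signatures.
    """
    if n_features < 10:
        raise ValueError("n_features must be >= 10 for a meaningful correlation")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(b"profile_pair")])
    )
    sig_sd = cfg_a.shared_signature_sd
    eps_sd = cfg_a.profile_noise_sd
    shared = (
        cfg_a.mechanism is not None
        and cfg_a.mechanism == cfg_b.mechanism
        and cfg_a.mechanism != "null"
    )
    s_a = rng.normal(0.0, sig_sd, n_features)
    s_b = s_a if shared else rng.normal(0.0, sig_sd, n_features)
    x = s_a + rng.normal(0.0, eps_sd, n_features)
    y = s_b + rng.normal(0.0, eps_sd, n_features)
    return _profile(cfg_a.name, x), _profile(cfg_b.name, y)


def generate_profile_panel(
    members: list[tuple[str, str | None]],
    n_features: int = 208,
    seed: int = 0,
    signature_sd: float = 1.0,
    noise_sd: float = math.sqrt((1 - DEFAULT_PROFILE_RHO) / DEFAULT_PROFILE_RHO),
) -> list[ResponseProfile]:
    """Panel of drug profiles with mechanism-shared latent signatures.

    ``members`` is a list of (drug name, mechanism label); drugs with the
    same mechanism label share one latent signature vector, drugs with a None
    label get independent signatures.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(b"profile_panel")])
    )
    signatures: dict[str, np.ndarray] = {}
    profiles = []
    for drug, mech in members:
        if mech is None:
            s = rng.normal(0.0, signature_sd, n_features)
        else:
            if mech not in signatures:
                signatures[mech] = rng.normal(0.0, signature_sd, n_features)
            s = signatures[mech]
        profiles.append(_profile(drug, s + rng.normal(0.0, noise_sd, n_features)))
    return profiles


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

DEFAULT_MEDIUM_TIMES_H = (0.0, 6.0, 12.0, 18.0, 24.0)
DEFAULT_PK_TIMES_MIN = (15.0, 30.0, 60.0, 120.0, 240.0)
DEFAULT_PLATE_TIMES_MIN = tuple(float(t) for t in range(0, 301, 5))


def generate_medium_timecourse(
    cfg: ScenarioConfig,
    condition: str,
    metabolite: str,
    times=DEFAULT_MEDIUM_TIMES_H,
    n_reps: int = 3,
    cv: float | None = None,
    seed: int | None = None,
) -> tuple[TimeCourse, TimeCourse]:
    """Medium amount and paired cell counts under exponential growth.

    The medium amount follows M(t) = M0 -/+ J N0 (e^{mu t} - 1)/mu (minus for
    glucose consumption, plus for lactate secretion; linear limit when
    mu = 0). Measurement noise is multiplicative log-normal on the cumulative
    consumed/secreted amount, capturing replicate-to-replicate variability in
    per-cell rates together with assay error on the change. Cell counts carry
    an independent 5% CV.
    """
    if condition not in cfg.fluxes or condition not in cfg.growth_rate:
        raise ValueError(f"condition {condition!r} has no fluxes/growth in scenario")
    if metabolite not in ("glucose", "lactate"):
        raise ValueError("medium metabolite must be 'glucose' or 'lactate'")
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at 0 and be strictly ascending")
    cv = cfg.intensity_cv if cv is None else cv
    j_glc, j_lac = cfg.fluxes[condition]
    J = j_glc if metabolite == "glucose" else j_lac
    sign = -1.0 if metabolite == "glucose" else 1.0
    mu = cfg.growth_rate[condition]
    n0 = cfg.n0_cells
    m0 = cfg.medium_m0.get(metabolite, 50.0 if metabolite == "glucose" else 0.0)

    if mu < 1e-12:
        integral = times.copy()
    else:
        integral = (np.exp(mu * times) - 1.0) / mu
    delta = J * n0 * integral * FMOL_TO_UMOL  # umol
    clean = m0 + sign * delta
    if np.any(clean < 0):
        raise ValueError(
            f"{metabolite} driven negative in condition {condition!r}; "
            "shorten the horizon or increase the medium amount"
        )

    local = cfg.reseeded(seed)
    rng = local.rng("medium", condition, metabolite)
    med_rows, cnt_rows = [], []
    for rep in range(1, n_reps + 1):
        noise = _lognormal_factor(rng, cv, times.size)
        cnt_noise = _lognormal_factor(rng, COUNT_CV if cv > 0 else 0.0, times.size)
        values = m0 + sign * delta * noise
        counts = n0 * np.exp(mu * times) * cnt_noise
        for t, v, c in zip(times, values, counts, strict=True):
            med_rows.append((t, v, rep))
            cnt_rows.append((t, c, rep))
    meta = {"scenario": cfg.name, "condition": condition, "seed": local.seed,
            "metabolite": metabolite, "units": "umol vs h", "n0": n0,
            "mu_true": mu, "J_true": J}
    medium = TimeCourse(
        series_id=f"{cfg.name}:{condition}:{metabolite}",
        kind="medium_amount",
        data=pd.DataFrame(med_rows, columns=["time", "value", "replicate"]),
        meta=meta,
    )
    counts_tc = TimeCourse(
        series_id=f"{cfg.name}:{condition}:cells",
        kind="cell_count",
        data=pd.DataFrame(cnt_rows, columns=["time", "value", "replicate"]),
        meta=meta,
    )
    return medium, counts_tc


def generate_pk_timecourse(
    cfg: ScenarioConfig,
    tissue: str,
    times=DEFAULT_PK_TIMES_MIN,
    n_reps: int = 3,
    cv: float = 0.15,
    seed: int | None = None,
) -> TimeCourse:
    """Tissue drug concentrations, mono-exponential decay from 15 min.

    C(t) = C_ref 2^{-(t - 15)/t_half} with mean-preserving log-normal noise;
    C_ref is the concentration at the first sampling time (15 min), the
    earliest point at which distribution is complete — the absorption phase
    is not modeled, so earlier times are rejected.
    """
    if tissue not in cfg.pk:
        raise ValueError(f"tissue {tissue!r} not in scenario PK map")
    times = np.asarray(times, dtype=float)
    if np.any(times < 15.0):
        raise ValueError("times before first sampling (15 min) are not modeled")
    c_ref, t_half = cfg.pk[tissue]
    if math.isfinite(t_half):
        clean = c_ref * np.power(2.0, -(times - 15.0) / t_half)
    else:
        clean = np.full(times.size, c_ref)
    local = cfg.reseeded(seed)
    rng = local.rng("pk", tissue)
    rows = []
    for rep in range(1, n_reps + 1):
        noise = _lognormal_factor(rng, cv, times.size)
        for t, v in zip(times, clean * noise, strict=True):
            rows.append((t, v, rep))
    return TimeCourse(
        series_id=f"{cfg.name}:{tissue}",
        kind="concentration",
        data=pd.DataFrame(rows, columns=["time", "value", "replicate"]),
        meta={"scenario": cfg.name, "tissue": tissue, "seed": local.seed,
              "units": "uM vs min", "t_half_true": t_half, "c_ref_true": c_ref},
    )


def generate_plate_trace(
    rate: float,
    plateau: float,
    times=DEFAULT_PLATE_TIMES_MIN,
    baseline: float = 0.05,
    drift: float = 2e-4,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    series_id: str = "well",
    replicate: int = 1,
) -> tuple[TimeCourse, TimeCourse]:
    """One well's saturating dye-reduction trace plus its reference channel.

    A590(t) = plateau (1 - e^{-(rate/plateau) t}) + baseline + drift t, so the
    initial slope of the signal equals ``rate``; A750 carries the same
    baseline drift but no signal, letting the analyzer background-subtract
    shared measurement artifacts.
    """
    times = np.asarray(times, dtype=float)
    if rate < 0 or plateau <= 0:
        raise ValueError("rate must be >= 0 and plateau > 0")
    if rate > 0:
        signal = plateau * (1.0 - np.exp(-(rate / plateau) * times))
    else:
        signal = np.zeros(times.size)
    a590 = signal + baseline + drift * times
    a750 = 0.6 * baseline + drift * times
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        a590 = a590 + rng.normal(0.0, noise_sd, times.size)
        a750 = a750 + rng.normal(0.0, noise_sd, times.size)

    def _tc(values, kind):
        return TimeCourse(
            series_id=f"{series_id}:{kind}",
            kind=kind,
            data=pd.DataFrame({"time": times, "value": values,
                               "replicate": replicate}),
            meta={"rate_true": rate, "plateau": plateau},
        )

    return _tc(a590, "absorbance590"), _tc(a750, "absorbance750")


def generate_biolog_plate(
    cfg: ScenarioConfig,
    drug: str = "drug",
    n_reps: int = 3,
    times=DEFAULT_PLATE_TIMES_MIN,
    seed: int | None = None,
) -> dict[str, dict[str, list[tuple[TimeCourse, TimeCourse]]]]:
    """Substrate-oxidation plate: traces per substrate x group x replicate.

    Control wells run at the scenario's base rate; drug wells are scaled by
    the per-substrate inhibition factor. Replicate rates carry log-normal
    variation, and every trace gets small additive absorbance noise.
    Returns {group: {substrate: [(a590, a750), ...]}}.
    """
    b = cfg.biolog
    if not b:
        raise ValueError(f"scenario {cfg.name!r} defines no plate parameters")
    local = cfg.reseeded(seed)
    rng = local.rng("biolog", drug)
    out: dict[str, dict[str, list]] = {"control": {}, drug: {}}
    for substrate in b["substrates"]:
        factor = b["inhibited"].get(substrate, 1.0)
        for group, scale in (("control", 1.0), (drug, factor)):
            wells = []
            for rep in range(1, n_reps + 1):
                rate = b["control_rate"] * scale * float(
                    _lognormal_factor(rng, b["rate_cv"], 1)[0]
                )
                wells.append(generate_plate_trace(
                    rate, b["plateau"], times=times,
                    noise_sd=b["absorbance_sd"], rng=rng,
                    series_id=f"{substrate}:{group}:r{rep}", replicate=rep,
                ))
            out[group][substrate] = wells
    return out


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

def generate_study(cfg: ScenarioConfig, n_reps: int = 10) -> GeneratedStudy:
    """Generate every table this scenario defines, with the truth echoed.

    ``n_reps`` is the replicate count of the profiling experiment. The
    default of 10 comes from a power analysis of the weakest signature
    component: detecting a 2-fold change at q < 0.05 among ~200 features at
    20% intensity CV with >= 95% power needs about ten replicates per group.
    """
    peak = None
    mids = None
    medium: list[TimeCourse] = []
    pk: list[TimeCourse] = []
    plates: list[TimeCourse] = []

    if cfg.pool_folds:
        tables = [generate_zebrafish_table(cfg, drug)
                  for drug in sorted(cfg.pool_folds)]
        peak = pd.concat(tables, ignore_index=True)
    elif cfg.true_fold:
        peak = generate_peak_table(cfg, n_reps=n_reps)
    if cfg.tracing:
        glc, _ = generate_tracer_panel(cfg, "U-13C6-glucose")
        gln, _ = generate_tracer_panel(cfg, "U-13C5-glutamine")
        mids = pd.concat([glc, gln], ignore_index=True)
    for condition in sorted(cfg.fluxes):
        for i, metabolite in enumerate(("glucose", "lactate")):
            med, cnt = generate_medium_timecourse(cfg, condition, metabolite)
            medium.append(med)
            if i == 0:  # one cell-count series per condition
                medium.append(cnt)
    for tissue in sorted(cfg.pk):
        pk.append(generate_pk_timecourse(cfg, tissue))
    if cfg.biolog:
        plate = generate_biolog_plate(cfg)
        for group in plate.values():
            for wells in group.values():
                for a590, a750 in wells:
                    plates.extend([a590, a750])
    return GeneratedStudy(peak_table=peak, isotopologue_tables=mids,
                          medium_timecourses=medium, pk_timecourses=pk,
                          plate_traces=plates, truth=cfg)
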