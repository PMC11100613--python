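"""Mechanistic readouts from corrected mass isotopologue distributions.

Interprets tracer-derived MIDs in terms of central-carbon metabolism:

* **Complementation** — whether the summed fractional enrichment from a
  glucose tracer and a glutamine tracer is conserved between treatment and
  control (a drop in glucose-derived labeling "fully compensated" by
  glutamine shows the product pool is still made, just from another source).
* **Anaplerosis indicator** — the balance between M+2 malate (pyruvate
  dehydrogenase route) and M+3 malate (pyruvate carboxylase / malic-enzyme
  anaplerosis) from a uniformly labeled glucose tracer.
* **Reductive carboxylation** — M+5 citrate from uniformly labeled glutamine
  (reverse IDH flux), with M+3 malate/aspartate marking carbon re-entry.
* **Acetyl-group deconvolution** — the 2-carbon acetyl MID on acetyl-CoA
  inferred from citrate, modeled as the convolution of the acetyl unit with
  the oxaloacetate pool (aspartate as proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .isotopes import as_mid, convolve_mids, fractional_enrichment

__all__ = [
    "KNOWN_TRACERS",
    "TracerPanel",
    "AnaplerosisResult",
    "AcetylDeconvolution",
    "complementation_summary",
    "compare_complementation",
    "anaplerosis_indicator",
    "reductive_carboxylation_indicator",
    "acetyl_deconvolution",
]

KNOWN_TRACERS = ("U-13C6-glucose", "U-13C5-glutamine", "13C2-acetate", "D2O")

#: Absolute tolerance on FE sums for the "full compensation" flag.
COMPENSATION_TOLERANCE = 0.05

#: Relative residual above which the citrate pool is flagged as violating
#: the simple acetyl (x) OAA product model.
DECONVOLUTION_RESIDUAL_THRESHOLD = 0.1


@dataclass
class TracerPanel:
    """Corrected MIDs for one condition under one tracer."""

    condition: str
    tracer: str
    mids: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tracer not in KNOWN_TRACERS:
            raise ValueError(
                f"unknown tracer {self.tracer!r}; known: {KNOWN_TRACERS}"
            )
        self.mids = {m: as_mid(v) for m, v in self.mids.items()}


def complementation_summary(
    glc_panel: TracerPanel,
    gln_panel: TracerPanel,
    metabolites: list[str],
) -> pd.DataFrame:
    """Per-metabolite fractional enrichment from each tracer and their sum.

    Metabolites missing from either panel are listed with NaN entries rather
    than silently dropped.
    """
    if glc_panel.condition != gln_panel.condition:
        raise ValueError("panels must share the condition")
    rows = []
    for met in metabolites:
        fe_glc = (fractional_enrichment(glc_panel.mids[met])
                  if met in glc_panel.mids else np.nan)
        fe_gln = (fractional_enrichment(gln_panel.mids[met])
                  if met in gln_panel.mids else np.nan)
        rows.append((met, fe_glc, fe_gln, fe_glc + fe_gln,
                     met not in glc_panel.mids or met not in gln_panel.mids))
    return pd.DataFrame(
        rows, columns=["metabolite", "fe_glc", "fe_gln", "fe_sum", "missing"]
    )


def compare_complementation(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    tolerance: float = COMPENSATION_TOLERANCE,
) -> pd.DataFrame:
    """Flag metabolites whose total tracer-derived enrichment is conserved.

    ``compensated`` is True when |FE_sum(treated) - FE_sum(control)| is within
    the tolerance despite a shifted glucose/glutamine split — the loss of
    glucose-derived flux is made up by the other carbon source.
    """
    merged = treated.merge(control, on="metabolite", suffixes=("_trt", "_ctrl"))
    merged["delta_sum"] = merged["fe_sum_trt"] - merged["fe_sum_ctrl"]
    merged["compensated"] = merged["delta_sum"].abs() <= tolerance
    return merged[["metabolite", "fe_glc_trt", "fe_gln_trt", "fe_sum_trt",
                   "fe_glc_ctrl", "fe_gln_ctrl", "fe_sum_ctrl",
                   "delta_sum", "compensated"]]


@dataclass(frozen=True)
class AnaplerosisResult:
    ratio: float | None   # f3 / (f2 + f3); None when undefined
    f2: float
    f3: float
    defined: bool


def anaplerosis_indicator(malate_mid) -> AnaplerosisResult:
    """Anaplerotic share of labeled malate: f3 / (f2 + f3).

    From uniformly 13C-labeled glucose, M+2 malate arises via pyruvate
    dehydrogenase and citrate synthase while M+3 arises from direct pyruvate
    carboxylation (or malic-enzyme exchange); the ratio tracks the switch
    away from PDH flux. Undefined (both fractions zero) is flagged rather
    than propagated as NaN.
    """
    mid = as_mid(malate_mid)
    if mid.size != 5:
        raise ValueError("malate MID must cover 4 carbons (length 5)")
    f2, f3 = float(mid[2]), float(mid[3])
    if f2 + f3 == 0:
        return AnaplerosisResult(ratio=None, f2=f2, f3=f3, defined=False)
    return AnaplerosisResult(ratio=f3 / (f2 + f3), f2=f2, f3=f3, defined=True)


def reductive_carboxylation_indicator(panel: TracerPanel) -> pd.DataFrame:
    """Reductive-carboxylation markers from a uniformly labeled glutamine panel.

    Reports citrate M+5 (the reverse-IDH route marker) plus the M+3 fraction
    of malate and aspartate (labeled carbon re-entering the TCA cycle after
    citrate cleavage).
    """
    if panel.tracer != "U-13C5-glutamine":
        raise ValueError("reductive carboxylation needs the U-13C5-glutamine tracer")
    if "citrate" not in panel.mids:
        raise ValueError("panel lacks a citrate MID")
    if panel.mids["citrate"].size != 7:
        raise ValueError("citrate MID must cover 6 carbons (length 7)")
    rows = [("citrate", "f5", float(panel.mids["citrate"][5]))]
    for met in ("malate", "aspartate"):
        if met in panel.mids:
            rows.append((met, "f3", float(panel.mids[met][3])))
    return pd.DataFrame(rows, columns=["metabolite", "isotopologue", "fraction"])


@dataclass(frozen=True)
class AcetylDeconvolution:
    acetyl: np.ndarray      # (a0, a1, a2)
    residual: float         # relative L2 misfit of the convolution model
    flagged: bool           # model violation: citrate not a simple product pool


def acetyl_deconvolution(
    citrate_mid,
    oaa_proxy_mid,
    residual_threshold: float = DECONVOLUTION_RESIDUAL_THRESHOLD,
) -> AcetylDeconvolution:
    """Infer the 2-carbon acetyl MID on acetyl-CoA from citrate labeling.

    Citrate is modeled as the condensation product of an acetyl unit (2C) and
    oxaloacetate (4C, with the measured aspartate MID as proxy); the acetyl
    MID ``a`` minimizes ||convolve(a, oaa) - citrate||_2 over the probability
    simplex. Solved as constrained least squares (SLSQP) from a deterministic
    uniform start; symmetry scrambling at fumarate is not modeled.
    """
    citrate = as_mid(citrate_mid)
    oaa = as_mid(oaa_proxy_mid)
    if citrate.size != oaa.size + 2:
        raise ValueError("citrate MID must cover two atoms more than the OAA proxy")

    # columns: oaa shifted by 0, 1, 2 mass units
    design = np.zeros((citrate.size, 3))
    for k in range(3):
        design[k:k + oaa.size, k] = oaa

    def objective(a):
        r = design @ a - citrate
        return float(r @ r)

    res = optimize.minimize(
        objective,
        x0=np.full(3, 1.0 / 3.0),
        jac=lambda a: 2.0 * design.T @ (design @ a - citrate),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 3,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(3)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    acetyl = np.clip(res.x, 0.0, None)
    acetyl /= acetyl.sum()
    misfit = np.linalg.norm(convolve_mids(acetyl, oaa) - citrate)
    residual = float(misfit / np.linalg.norm(citrate))
    return AcetylDeconvolution(acetyl=acetyl, residual=residual,
                               flagged=residual > residual_threshold)
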