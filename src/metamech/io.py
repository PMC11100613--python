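"""Pipeline orchestration, table IO, validation, and the run manifest.

The pipeline runs simulate -> correct -> trace -> signature -> kinetics over
tidy CSV files (UTF-8, comma-separated, header row, "." decimal):

* ``peaks.csv``       metabolite, compartment, drug, dose, replicate, intensity
* ``mids.csv``        metabolite, tracer, element, n_atoms, mass_shift,
                      intensity, replicate
* ``corrected.csv``   mids.csv plus corrected_fraction and residual
* ``timecourse.csv``  series_id, kind, time, value, replicate
* ``truth.json``      scenario ground-truth echo

Every run directory gets exactly one ``manifest.json`` recording the pipeline
version, a config hash, the master seed, output digests, stage timings, and
all warnings emitted by any stage, so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import isotopes, kinetics, signature, synthetic, tracing

__version__ = "0.1.0"

__all__ = [
    "SCHEMAS",
    "ValidationReport",
    "validate_table",
    "write_study",
    "run_pipeline",
]

SCHEMAS = {
    "peaks": {
        "required": ["metabolite", "compartment", "drug", "dose",
                     "replicate", "intensity"],
        "key": ["metabolite", "compartment", "drug", "dose", "replicate"],
        "numeric": ["dose", "replicate", "intensity"],
    },
    "mids": {
        "required": ["metabolite", "tracer", "element", "n_atoms",
                     "mass_shift", "intensity", "replicate"],
        "key": ["metabolite", "tracer", "element", "mass_shift", "replicate"],
        "numeric": ["n_atoms", "mass_shift", "intensity", "replicate"],
    },
    "timecourse": {
        "required": ["series_id", "kind", "time", "value", "replicate"],
        "key": ["series_id", "time", "replicate"],
        "numeric": ["time", "value", "replicate"],
    },
}


@dataclass
class ValidationReport:
    table: str
    passed: bool
    problems: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"{self.table}: {status}"] + [f"  - {p}" for p in self.problems]
        return "\n".join(lines)


def validate_table(path: str | Path, schema: str) -> ValidationReport:
    """Validate a CSV against a named schema; always returns a report.

    Checks column presence, numeric types, key uniqueness, and type
    invariants (non-negative replicate/dose, intensities above the negative
    clamp threshold for spectra). Problems cite 1-based data line numbers.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    problems: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file is a failed report, not a crash
        return ValidationReport(schema, False, [f"{path}: unreadable ({exc})"])

    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {', '.join(missing)}")
        return ValidationReport(schema, False, problems)

    for col in spec["numeric"]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            problems.append(f"column {col}: non-numeric values at lines {lines}")

    dup = df.duplicated(subset=spec["key"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        problems.append(
            f"duplicated key {tuple(spec['key'])} at lines {lines}"
        )

    if schema == "peaks":
        counts = df.groupby(["metabolite", "drug", "dose"]).size()
        under = counts[counts < 2]
        if len(under):
            problems.append(
                f"{len(under)} (metabolite, drug, dose) groups have < 2 replicates"
            )
        if not ((df["drug"] == "vehicle") | (df["dose"] == 0)).any():
            problems.append("no vehicle/control group (drug 'vehicle' or dose 0)")
    if schema == "mids":
        inten = pd.to_numeric(df["intensity"], errors="coerce")
        spectrum_max = inten.groupby(
            [df["metabolite"], df["tracer"], df["replicate"]]
        ).transform("max")
        too_negative = inten < -isotopes.NEGATIVE_CLAMP_FRACTION * spectrum_max
        if too_negative.any():
            lines = (df.index[too_negative] + 2).tolist()[:10]
            problems.append(
                "negative intensities beyond the "
                f"{isotopes.NEGATIVE_CLAMP_FRACTION:.0%} clamp threshold "
                f"at lines {lines}"
            )
    if schema == "timecourse":
        if (pd.to_numeric(df["time"], errors="coerce") < 0).any():
            problems.append("negative times present")

    return ValidationReport(schema, not problems, problems)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def write_study(study: synthetic.GeneratedStudy, out_dir: str | Path) -> list[Path]:
    """Write every table of a generated study to tidy CSVs plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if study.peak_table is not None:
        _write_csv(study.peak_table, out / "peaks.csv")
        written.append(out / "peaks.csv")
    if study.isotopologue_tables is not None:
        _write_csv(study.isotopologue_tables, out / "mids.csv")
        written.append(out / "mids.csv")
    tcs = (study.medium_timecourses + study.pk_timecourses + study.plate_traces)
    if tcs:
        _write_csv(pd.concat([tc.to_rows() for tc in tcs], ignore_index=True),
                   out / "timecourse.csv")
        written.append(out / "timecourse.csv")
    truth = study.truth.to_dict()
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    written.append(out / "truth.json")
    return written


def correct_mids_table(
    mids: pd.DataFrame,
    tracer_purity: float = 1.0,
) -> pd.DataFrame:
    """Natural-abundance-correct every spectrum in a mids table.

    Adds ``corrected_fraction`` and ``residual`` columns; spectra are grouped
    by (metabolite, tracer, element, replicate) and ordered by mass shift.
    """
    out_rows = []
    matrices: dict[tuple[int, float], isotopes.CorrectionMatrix] = {}
    for (met, tracer, element, rep), grp in mids.groupby(
        ["metabolite", "tracer", "element", "replicate"], sort=True
    ):
        grp = grp.sort_values("mass_shift")
        n = int(grp["n_atoms"].iloc[0])
        p = isotopes.NATURAL_ABUNDANCE[element]
        key = (n, tracer_purity)
        if key not in matrices:
            matrices[key] = isotopes.build_correction_matrix(n, p, tracer_purity)
        result = isotopes.correct_spectrum(
            grp["intensity"].to_numpy(dtype=float), matrices[key]
        )
        for shift, raw_i, frac in zip(
            grp["mass_shift"], grp["intensity"], result.mid, strict=True
        ):
            out_rows.append((met, tracer, element, n, int(shift), raw_i, rep,
                             frac, result.residual, result.flagged))
    return pd.DataFrame(
        out_rows,
        columns=["metabolite", "tracer", "element", "n_atoms", "mass_shift",
                 "intensity", "replicate", "corrected_fraction", "residual",
                 "flagged"],
    )


def panels_from_corrected(corrected: pd.DataFrame, condition: str = "treated"
                          ) -> dict[str, tracing.TracerPanel]:
    """Average corrected MIDs across replicates into per-tracer panels."""
    panels = {}
    for tracer, grp in corrected.groupby("tracer"):
        mids = {}
        for met, sub in grp.groupby("metabolite"):
            mean = (
                sub.groupby("mass_shift")["corrected_fraction"].mean()
                .sort_index().to_numpy()
            )
            mids[met] = mean / mean.sum()
        panels[tracer] = tracing.TracerPanel(condition=condition,
                                             tracer=tracer, mids=mids)
    return panels


def tracing_report(panels: dict[str, tracing.TracerPanel]) -> tuple[pd.DataFrame, dict]:
    """Mechanistic indicator table and JSON-ready summary from tracer panels."""
    rows = []
    summary: dict = {}
    glc = panels.get("U-13C6-glucose")
    gln = panels.get("U-13C5-glutamine")
    if glc is not None and "malate" in glc.mids:
        ana = tracing.anaplerosis_indicator(glc.mids["malate"])
        rows.append(("malate", "anaplerosis_f3_over_f2f3",
                     np.nan if ana.ratio is None else ana.ratio))
        rows.append(("malate", "f2", ana.f2))
        rows.append(("malate", "f3", ana.f3))
        summary["anaplerosis"] = None if ana.ratio is None else ana.ratio
    if glc is not None and {"citrate", "aspartate"} <= glc.mids.keys():
        dec = tracing.acetyl_deconvolution(glc.mids["citrate"],
                                           glc.mids["aspartate"])
        for i, a in enumerate(dec.acetyl):
            rows.append(("acetyl_coa_acetyl", f"deconvolved_a{i}", float(a)))
        rows.append(("acetyl_coa_acetyl", "deconvolution_residual", dec.residual))
        summary["acetyl_deconvolution"] = {
            "acetyl": dec.acetyl.tolist(),
            "residual": dec.residual,
            "model_violation": dec.flagged,
        }
    if gln is not None and "citrate" in gln.mids:
        red = tracing.reductive_carboxylation_indicator(gln)
        for _, row in red.iterrows():
            rows.append((row["metabolite"],
                         f"reductive_{row['isotopologue']}", row["fraction"]))
        summary["reductive_citrate_f5"] = float(
            red.loc[red["metabolite"] == "citrate", "fraction"].iloc[0]
        )
    if glc is not None and gln is not None:
        shared = sorted(set(glc.mids) & set(gln.mids))
        comp = tracing.complementation_summary(glc, gln, shared)
        for _, row in comp.iterrows():
            rows.append((row["metabolite"], "fe_sum", row["fe_sum"]))
        summary["complementation"] = comp.set_index("metabolite")["fe_sum"].to_dict()
    report = pd.DataFrame(rows, columns=["metabolite", "indicator", "value"])
    return report, summary


def signature_reports(
    peaks: pd.DataFrame, drug: str
) -> tuple[pd.DataFrame, pd.DataFrame, signature.MechanismCall]:
    """Volcano table (top dose), dose-resolved profiles, and mechanism call."""
    doses = sorted(d for d in peaks.loc[peaks["drug"] == drug, "dose"].unique()
                   if d > 0)
    if not doses:
        raise ValueError(f"no dosed rows for drug {drug!r}")
    profiles = [signature.fold_changes(peaks, drug, d) for d in doses]
    trends = {}
    if len(doses) >= 2:
        for met in signature.FASN_SIGNATURE:
            if met in set(peaks["metabolite"]):
                trends[met] = signature.dose_trend(peaks, drug, met)
    call = signature.classify_mechanism(profiles, trends)
    volcano = profiles[-1].to_frame()
    all_profiles = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    return volcano, all_profiles, call


def _flux_report(timecourses: list[kinetics.TimeCourse]) -> pd.DataFrame:
    """Per-condition growth and flux estimates plus the fold/stoichiometry row."""
    by_cond: dict[str, dict[str, kinetics.TimeCourse]] = {}
    for tc in timecourses:
        cond = tc.meta.get("condition")
        if cond is None:
            continue
        label = "cells" if tc.kind == "cell_count" else tc.meta.get("metabolite")
        by_cond.setdefault(cond, {})[label] = tc

    rows = []
    estimates: dict[tuple[str, str], kinetics.FluxEstimate] = {}
    for cond, series in sorted(by_cond.items()):
        if "cells" not in series:
            continue
        growth = kinetics.fit_growth(series["cells"])
        n0 = series["cells"].meta.get("n0", growth.n0_fit)
        rows.append((cond, "growth_rate", growth.mu, growth.se))
        for met, direction in (("glucose", "consumption"),
                               ("lactate", "secretion")):
            if met not in series:
                continue
            est = kinetics.exoflux(series[met], growth.mu, n0, direction)
            estimates[(cond, met)] = est
            rows.append((cond, f"J_{met}", est.J, est.se))
    report = pd.DataFrame(rows, columns=["condition", "quantity", "value", "se"])
    needed = {("treated", "glucose"), ("control", "glucose"),
              ("treated", "lactate"), ("control", "lactate")}
    if needed <= estimates.keys():
        comp = kinetics.flux_fold_and_stoichiometry(
            estimates[("treated", "glucose")], estimates[("control", "glucose")],
            estimates[("treated", "lactate")], estimates[("control", "lactate")],
        )
        extra = pd.DataFrame(
            [("treated_vs_control", "fold_glucose", comp.fold_glc, np.nan),
             ("treated_vs_control", "fold_lactate", comp.fold_lac, np.nan),
             ("treated_vs_control", "delta_lactate_per_glucose",
              np.nan if comp.delta_ratio is None else comp.delta_ratio, np.nan)],
            columns=report.columns,
        )
        report = pd.concat([report, extra], ignore_index=True)
    return report


def _pk_report(timecourses: list[kinetics.TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in timecourses:
        fit = kinetics.pk_fit(tc)
        rows.append((tc.series_id, tc.meta.get("tissue", ""),
                     fit.c_first,
                     np.nan if fit.t_half is None else fit.t_half,
                     fit.r_squared, fit.message))
    return pd.DataFrame(rows, columns=["series_id", "tissue", "c_first_uM",
                                       "t_half_min", "r_squared", "note"])


def _biolog_report(timecourses: list[kinetics.TimeCourse]) -> pd.DataFrame:
    """Pair absorbance channels by well, estimate rates, and test per substrate."""
    wells: dict[str, dict[str, kinetics.TimeCourse]] = {}
    for tc in timecourses:
        well_id = tc.series_id.rsplit(":", 1)[0]
        wells.setdefault(well_id, {})[tc.kind] = tc
    rate_rows = []
    for well_id, channels in sorted(wells.items()):
        if {"absorbance590", "absorbance750"} != channels.keys():
            continue
        substrate, group, rep = well_id.split(":")
        rate = kinetics.biolog_initial_rate(channels["absorbance590"],
                                            channels["absorbance750"])
        rate_rows.append((substrate, group, int(rep.lstrip("r")), rate.rate))
    rates = pd.DataFrame(rate_rows,
                         columns=["substrate", "group", "replicate", "rate"])
    return kinetics.biolog_compare(rates)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    try:
        import yaml
        return yaml.safe_load(text)
    except ImportError:  # pragma: no cover - yaml is a soft dependency
        return json.loads(text)


def run_pipeline(config, out_dir: str | Path) -> Path:
    """Run simulate -> correct -> trace -> signature -> kinetics -> manifest.

    ``config`` is a mapping (or a YAML/JSON file) with at least ``scenario``
    and ``seed``; optional keys: ``n_reps`` (profiling replicates, default
    10). Outputs are tidy CSVs in ``out_dir``; re-running with an identical
    config and seed reproduces byte-identical files.
    """
    cfg_dict = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scenario = cfg_dict.get("scenario", "vehicle")
    seed = int(cfg_dict.get("seed", 0))
    n_reps = int(cfg_dict.get("n_reps", 10))
    cfg = synthetic.make_scenario(scenario, seed=seed)

    timings: dict[str, float] = {}
    caught: list[str] = []
    manifest: dict = {
        "pipeline_version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": seed,
        "scenario": scenario,
    }

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        t0 = time.perf_counter()
        study = synthetic.generate_study(cfg, n_reps=n_reps)
        write_study(study, out)
        timings["simulate"] = time.perf_counter() - t0

        if study.isotopologue_tables is not None:
            t0 = time.perf_counter()
            corrected = correct_mids_table(study.isotopologue_tables)
            _write_csv(corrected, out / "corrected.csv")
            timings["correct"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            panels = panels_from_corrected(corrected, condition=scenario)
            report, summary = tracing_report(panels)
            _write_csv(report, out / "tracing_report.csv")
            (out / "tracing_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
            timings["trace"] = time.perf_counter() - t0

        if study.peak_table is not None:
            t0 = time.perf_counter()
            drugs = [d for d in study.peak_table["drug"].unique()
                     if d != "vehicle"]
            calls = {}
            volcanoes, profs = [], []
            for drug in sorted(drugs):
                sub = study.peak_table
                n_doses = sub.loc[sub["drug"] == drug, "dose"].nunique()
                if n_doses >= 2:
                    volcano, profiles_df, call = signature_reports(sub, drug)
                    calls[drug] = {
                        "label": call.label,
                        "fasn_score": call.fasn_score,
                        "complex_i_score": call.complex_i_score,
                        "missing_markers": call.missing_markers,
                        "thresholds": call.thresholds,
                    }
                else:  # single-exposure design (e.g. whole-embryo pools)
                    dose = float(sub.loc[sub["drug"] == drug, "dose"].iloc[0])
                    prof = signature.fold_changes(sub, drug, dose)
                    volcano = prof.to_frame()
                    profiles_df = volcano
                    calls[drug] = {"label": "not_applicable",
                                   "note": "single-dose design"}
                volcanoes.append(volcano)
                profs.append(profiles_df)
            _write_csv(pd.concat(volcanoes, ignore_index=True),
                       out / "volcano.csv")
            _write_csv(pd.concat(profs, ignore_index=True),
                       out / "profiles.csv")
            (out / "calls.json").write_text(
                json.dumps(calls, indent=2, sort_keys=True)
            )
            timings["signature"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if study.medium_timecourses:
            _write_csv(_flux_report(study.medium_timecourses),
                       out / "flux_report.csv")
        if study.pk_timecourses:
            _write_csv(_pk_report(study.pk_timecourses), out / "pk_report.csv")
        if study.plate_traces:
            _write_csv(_biolog_report(study.plate_traces),
                       out / "biolog_report.csv")
        if study.medium_timecourses or study.pk_timecourses or study.plate_traces:
            timings["kinetics"] = time.perf_counter() - t0

        seen = set()
        for w in wlist:
            msg = str(w.message)
            if msg not in seen:
                seen.add(msg)
                caught.append(msg)

    manifest["stage_timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    manifest["warnings"] = caught
    manifest["output_digests"] = {
        p.name: _digest(p) for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
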