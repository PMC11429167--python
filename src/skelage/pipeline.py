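"""End-to-end orchestration: records → statistics → demography → growth.

``analyze`` reproduces the study protocol on any records CSV or
in-memory dataset: per-sex descriptives for age and SVL, a
Shapiro–Wilk normality gate selecting the nonparametric branch,
Mann–Whitney sex comparisons, Spearman age–SVL correlations per sex,
Robson–Chapman survival with Seber life expectancy, the sexual size
dimorphism index (both sign conventions), life-history summaries, and
von Bertalanffy growth fits per sex. The report is a plain JSON-able
dict: full-precision values plus display roundings (2 dp for
S/ESP/means, 3 dp for SDI) so any displayed figure is traceable to one
upstream operation. Failed stages are recorded and independent stages
still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import __version__, demography, growth, simulate, stats
from .demography import AgeCoding, SDIVariant
from .records import (
    AgeClassCounts,
    LifeStage,
    Sex,
    StudyDataset,
    aggregate_age_classes,
    read_records,
    write_records,
)

__all__ = [
    "analyze",
    "analyze_dataset",
    "run_simulation",
    "run_recovery",
    "validate_report",
    "load_sim_config",
]

log = logging.getLogger("skelage.pipeline")

_SEXES = (("male", Sex.MALE), ("female", Sex.FEMALE))


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(report: dict, name: str, fn):
    """Run one pipeline stage, recording success/failure without aborting."""
    try:
        out = fn()
        report["stages"][name] = {"status": "ok"}
        return out
    except Exception as exc:  # degradation contract: downstream stages still run
        log.warning("stage %s failed: %s", name, exc)
        report["stages"][name] = {"status": "failed", "error": str(exc)}
        return None


def analyze_dataset(
    dataset: StudyDataset,
    *,
    input_label: str = "<in-memory>",
    alpha: float = 0.05,
    coding: AgeCoding = AgeCoding.RAW_AGE,
    esp_round_s_to: int = 2,
    config: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the full analysis on an in-memory dataset; returns the report dict."""
    config = dict(config or {})
    config.update({"alpha": alpha, "coding": coding.value, "esp_round_s_to": esp_round_s_to})
    report: dict[str, Any] = {
        "provenance": {
            "input": input_label,
            "package_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": _config_hash(config),
        },
        "stages": {},
        "descriptives": {},
        "demography": {},
        "dimorphism": {},
        "comparisons": {},
        "correlations": {},
        "growth": {},
    }

    adults = {name: dataset.filter(sex=sex, life_stage=LifeStage.ADULT) for name, sex in _SEXES}

    # descriptive statistics and the normality gate, per sex and variable
    for name, sub in adults.items():
        for var, values in (("age", sub.ages()), ("svl", sub.svls())):
            entry = _stage(
                report, f"describe/{name}/{var}", lambda v=values: asdict(stats.describe(v))
            )
            if entry is not None:
                gate = _stage(
                    report,
                    f"shapiro/{name}/{var}",
                    lambda v=values: asdict(stats.shapiro_wilk_gate(v, alpha=alpha)),
                )
                entry["shapiro"] = gate
                entry["mean_2dp"] = round(entry["mean"], 2)
                entry["sd_2dp"] = round(entry["sd"], 2)
                report["descriptives"].setdefault(name, {})[var] = entry

    # demography per sex: survival, life expectancy, life-history summary
    for name, sex in _SEXES:
        counts = aggregate_age_classes(dataset, sex=sex, life_stage=LifeStage.ADULT)

        def demog(counts: AgeClassCounts = counts) -> dict[str, Any]:
            est = demography.robson_chapman_survival(counts, coding)
            esp_rounded = demography.seber_esp(est, round_s_to=esp_round_s_to)
            esp_full = demography.seber_esp(est)
            lh = demography.life_history_summary(counts)
            return {
                "S": est.s,
                "S_2dp": round(est.s, 2),
                "T": est.t,
                "R": est.r,
                "coding": est.coding.value,
                "esp_rounded": esp_rounded.esp,
                "esp_rounded_2dp": round(esp_rounded.esp, 2),
                "esp_full": esp_full.esp,
                "maturity": lh.age_at_maturity,
                "longevity": lh.longevity,
                "reproductive_lifespan": lh.reproductive_lifespan,
            }

        out = _stage(report, f"demography/{name}", demog)
        if out is not None:
            report["demography"][name] = out

    # sexual size dimorphism from adult mean SVLs
    def dimorphism() -> dict[str, Any]:
        mm = stats.describe(adults["male"].svls()).mean
        mf = stats.describe(adults["female"].svls()).mean
        rp1 = demography.size_dimorphism_index(mm, mf, SDIVariant.RATIO_PLUS_ONE)
        lg = demography.size_dimorphism_index(mm, mf, SDIVariant.LOVICH_GIBBONS)
        return {
            "mean_male_svl": mm,
            "mean_female_svl": mf,
            "sdi_ratio_plus_one": rp1.sdi,
            "sdi_ratio_plus_one_3dp": round(rp1.sdi, 3),
            "sdi_lovich_gibbons": lg.sdi,
            "larger_sex": rp1.larger_sex,
        }

    out = _stage(report, "dimorphism", dimorphism)
    if out is not None:
        report["dimorphism"] = out

    # nonparametric sex comparisons (age, SVL)
    for var in ("age", "svl"):
        def compare(var=var) -> dict[str, Any]:
            xm = adults["male"].ages() if var == "age" else adults["male"].svls()
            xf = adults["female"].ages() if var == "age" else adults["female"].svls()
            res = stats.mann_whitney_u(xm, xf)
            return {
                "u": res.u,
                "u1": res.u1,
                "u2": res.u2,
                "p": res.p,
                "method": res.method.value,
                "n": [len(xm), len(xf)],
            }

        out = _stage(report, f"mann_whitney/{var}", compare)
        if out is not None:
            report["comparisons"][var] = out

    # age–SVL correlation per sex
    for name, sub in adults.items():
        def correlate(sub=sub) -> dict[str, Any]:
            res = stats.spearman(sub.ages(), sub.svls())
            return {
                "rho": res.rho,
                "rho_2dp": round(res.rho, 2),
                "s_stat": res.s_stat,
                "p": res.p,
                "n": res.n,
                "ci95": list(res.ci95) if res.ci95 else None,
            }

        out = _stage(report, f"spearman/{name}", correlate)
        if out is not None:
            report["correlations"][name] = out

    # von Bertalanffy growth per sex (all measured life stages)
    def fit_growth() -> dict[str, Any]:
        fits = growth.fit_by_sex(dataset)
        entry: dict[str, Any] = {}
        for sex, fit in fits.items():
            entry[sex.name.lower()] = {
                "svl_max": fit.params.svl_max,
                "k": fit.params.k,
                "svl_met": fit.params.svl_met,
                "t_met": fit.params.t_met,
                "rss": fit.rss,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
            }
        if Sex.MALE in fits and Sex.FEMALE in fits:
            km, kf = fits[Sex.MALE].params.k, fits[Sex.FEMALE].params.k
            entry["k_ordering"] = "male > female" if km > kf else ("female > male" if kf > km else "equal")
        else:
            entry["k_ordering"] = "undefined (fewer than two sexes fitted)"
        return entry

    out = _stage(report, "growth", fit_growth)
    if out is not None:
        report["growth"] = out

    validate_report(report)
    return report


def analyze(
    input_path: str | Path,
    out_path: str | Path | None = None,
    **options: Any,
) -> dict[str, Any]:
    """Analyze a records CSV; optionally write the JSON report."""
    dataset = read_records(input_path)
    report = analyze_dataset(dataset, input_label=str(input_path), **options)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    return report


# ---------------------------------------------------------------------------
# Simulation / recovery entry points
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path, seed: int | None = None) -> simulate.SimConfig:
    """Read a SimConfig from YAML/JSON; ``seed`` overrides/supplies the seed."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "growth_by_sex" in raw:
        raw["growth_by_sex"] = {s: tuple(v) for s, v in raw["growth_by_sex"].items()}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError("an explicit seed is required (in the config file or via --seed)")
    return simulate.SimConfig(**raw)


def run_simulation(config: simulate.SimConfig, out_csv: str | Path) -> Path:
    """Write a simulated dataset as records CSV plus a truth sidecar JSON."""
    sim = simulate.generate_population(config)
    out_csv = Path(out_csv)
    write_records(sim.dataset, out_csv)
    truth = dict(config.__dict__)
    truth["growth_by_sex"] = {s: list(v) for s, v in config.growth_by_sex.items()}
    sidecar = out_csv.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    return sidecar


def run_recovery(config: simulate.SimConfig, n_replicates: int, out_csv: str | Path | None = None):
    """Run the parameter-recovery harness; optionally write the CSV summary."""
    table = simulate.recovery_experiment(config, n_replicates)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


# ---------------------------------------------------------------------------
# Report schema validation (structural subset of JSON Schema)
# ---------------------------------------------------------------------------

_TYPES = {"object": dict, "string": str, "number": (int, float), "array": list}


def _check(instance: Any, schema: dict[str, Any], path: str) -> list[str]:
    errors: list[str] = []
    expected = schema.get("type")
    if expected and not isinstance(instance, _TYPES.get(expected, object)):
        errors.append(f"{path}: expected {expected}, got {type(instance).__name__}")
        return errors
    if expected == "object":
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    return errors


def validate_report(report: dict[str, Any]) -> None:
    """Validate a report against the shipped schema; raises on mismatch."""
    schema = json.loads(
        resources.files("skelage.schemas").joinpath("report.schema.json").read_text()
    )
    errors = _check(report, schema, "$")
    if errors:
        raise ValueError("report schema violation: " + "; ".join(errors))
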