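"""End-to-end orchestration: data in, full result bundle out.

A run reads (or generates) the three record streams, applies the
demographic exclusions, bins records into triennia, estimates the
phenologies, runs the demographic test battery and sex-bias bootstrap,
estimates per-bin core seasons and the median-date trend, and writes
delimited tables, a run log, and one machine-readable JSON summary.

Reproducibility: a single master seed is supplied; every stochastic
stage draws from a substream derived by hashing the stage name together
with the master seed, so adding or reordering stages does not shift the
streams of the others.  Two runs with the same configuration and seed
produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import data_io, demographics, phenology, season_expansion
from .data_io import IncidentCriteria, bin_label
from .demographics import BootstrapConfig
from .season_expansion import PerturbationConfig
from .synthetic_data import (SyntheticConfig, gen_detections, gen_incidents,
                             gen_strandings, published_scale_config)

log = logging.getLogger("strandphen")

#: paper-gap choices in effect for every run, echoed into the run log
DIALECT = {
    "chi_squared_continuity": "Yates correction ON for 2x2 tables",
    "quotient_definition": "shark_total / nonshark_total (fraction also emitted)",
    "kernel": "wrapped Gaussian, Silverman bandwidth floored at 3 d unless set",
    "sigma_rule_default": "MAD / sqrt(n), floored at 1 d",
    "truncation": "observed date +/- 365 d",
    "wilcoxon_mode": "rank_sum on per-bin observed male-bias values (logged)",
    "months": "30.44 days per month",
}


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Derived substream seed: stable hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to the three CSV streams) or
    ``synthetic`` must be set.
    """

    seed: int = 0
    out_dir: str | Path = "run_output"
    inputs: Mapping[str, str] | None = None       # keys: strandings/incidents/detections
    synthetic: SyntheticConfig | None = None
    column_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    start_year: int = 1997
    width_years: int = 3
    bandwidth: float | str = "auto"
    incident_criteria: IncidentCriteria = field(default_factory=IncidentCriteria)
    bootstrap: BootstrapConfig | None = None
    perturbation: PerturbationConfig | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise PipelineError(
                "configuration: exactly one of inputs / synthetic must be set")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


@_stage("acquire")
def _acquire(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic,
                                  seed=stage_seed(cfg.seed, "synthetic"))
        strandings = gen_strandings(syn)
        shark_det, seal_det = gen_detections(syn)
        incidents, _ = gen_incidents(syn)
        return strandings, [shark_det, seal_det], incidents, []
    assert cfg.inputs is not None
    maps = cfg.column_maps
    strandings, issues = data_io.read_strandings(
        cfg.inputs["strandings"], maps.get("strandings"))
    incidents, inc_issues = data_io.read_incidents(
        cfg.inputs["incidents"], maps.get("incidents"))
    detections = data_io.read_detections(
        cfg.inputs["detections"], maps.get("detections"))
    return strandings, detections, incidents, list(issues) + list(inc_issues)


@_stage("phenology")
def _phenology(cfg: RunConfig, strandings, detections, incidents):
    out: dict[str, Any] = {}
    shark_strand_doys = [data_io.doy(r.date) for r in strandings
                         if r.cause == "shark"]
    densities = {}
    if len(set(shark_strand_doys)) >= 2:
        densities["stranding_shark"] = phenology.estimate_density(
            shark_strand_doys, bandwidth=cfg.bandwidth)
    kept = data_io.filter_incidents(incidents, cfg.incident_criteria)
    out["incidents_retained"] = len(kept)
    inc_doys = [data_io.doy(r.date) for r in kept]
    if len(set(inc_doys)) >= 2:
        densities["human_incident"] = phenology.estimate_density(
            inc_doys, bandwidth=cfg.bandwidth)
    for series in detections:
        try:
            densities[f"detection_{series.species}"] = phenology.relative_density(
                series, bandwidth=cfg.bandwidth)
        except ValueError:
            log.warning("series %s has no positive counts; skipped", series.species)
    out["peaks"] = {k: phenology.peak_doy(d) for k, d in densities.items()}
    if "stranding_shark" in densities and "detection_shark" in densities:
        out["lag_stranding_to_detection_peak"] = phenology.phenology_lag(
            densities["stranding_shark"], densities["detection_shark"], "peak")
    out["bandwidths"] = {k: d.bandwidth for k, d in densities.items()}
    return densities, out


@_stage("demographics")
def _demographics(cfg: RunConfig, included):
    out: dict[str, Any] = {"tests": {}, "bias": {}}
    sexed = [r for r in included if r.sex in ("M", "F")]
    boot = cfg.bootstrap or BootstrapConfig(seed=stage_seed(cfg.seed, "bootstrap"))

    tests = {
        "sex_x_cause": (None, "sex", "cause", ("M", "F"), ("shark", "other")),
        "maturity_x_cause_males": (lambda r: r.sex == "M", "age_class", "cause",
                                   ("mature", "immature"), ("shark", "other")),
        "maturity_x_cause_females": (lambda r: r.sex == "F", "age_class", "cause",
                                     ("mature", "immature"), ("shark", "other")),
    }
    for name, (filt, rf, cf, rl, cl) in tests.items():
        try:
            table = demographics.build_contingency(sexed, rf, cf, filt,
                                                   row_levels=rl, col_levels=cl)
            res = demographics.chi_squared(table, yates=True)
            out["tests"][name] = {"chi_squared": res.value, "df": res.df,
                                  "p_value": res.p_value, "yates": res.correction,
                                  "cells": table.cells.tolist()}
        except ValueError as exc:
            out["tests"][name] = {"error": str(exc)}

    for maturity in ("mature", "immature"):
        for cause in ("shark", "other"):
            stratum = [r for r in sexed
                       if r.age_class == maturity and r.cause == cause]
            if not stratum:
                continue
            for grouping in ("pooled", "per_bin"):
                s = demographics.bootstrap_bias(
                    stratum, boot, grouping=grouping,
                    group_label=f"{maturity}_{cause}",
                    start_year=cfg.start_year, width_years=cfg.width_years)
                out["bias"][f"{maturity}_{cause}_{grouping}"] = {
                    "n": s.n_records, "male_count": s.male_count,
                    "median": s.median, "ci": [s.ci_lower, s.ci_upper],
                    "n_replicates": s.n_replicates}

    # per-bin observed male bias, shark vs other causes, among matures
    mature = [r for r in sexed if r.age_class == "mature"]
    shark_bias = demographics.observed_bias_by_bin(
        [r for r in mature if r.cause == "shark"], cfg.start_year, cfg.width_years)
    other_bias = demographics.observed_bias_by_bin(
        [r for r in mature if r.cause == "other"], cfg.start_year, cfg.width_years)
    common = sorted(set(shark_bias) & set(other_bias))
    if len(common) >= 2:
        res = demographics.wilcoxon([shark_bias[b] for b in common],
                                    [other_bias[b] for b in common],
                                    mode="rank_sum")
        out["tests"]["mature_bias_shark_vs_other"] = {
            "W": res.value, "p_value": res.p_value, "mode": "rank_sum",
            "method": res.method, "n_bins": len(common)}
    return out


@_stage("season")
def _season(cfg: RunConfig, binned):
    pert = cfg.perturbation or PerturbationConfig(
        seed=stage_seed(cfg.seed, "perturbation"))
    shark_bins = {b: [r for r in recs if r.cause == "shark"]
                  for b, recs in binned.items()}
    shark_bins = {b: r for b, r in shark_bins.items() if r}
    seasons = season_expansion.season_by_bin(shark_bins, pert)
    rows = [{"bin": b, "label": bin_label(b, cfg.start_year, cfg.width_years),
             "start_doy": e.start_doy, "end_doy": e.end_doy,
             "length_days": e.length_days, "length_months": e.length_months,
             "n": e.n_records, "low_confidence": e.low_confidence}
            for b, e in sorted(seasons.items())]
    out: dict[str, Any] = {"bins": rows}
    if len(seasons) >= 2:
        for level in ("replicate", "bin"):
            t = season_expansion.median_trend(seasons, level=level)
            out[f"trend_{level}"] = {
                "slope_days_per_bin": t.slope, "intercept": t.intercept,
                "r_squared": t.r_squared, "p_value": t.p_value,
                "stderr": t.stderr, "total_advance_days": t.total_advance,
                "n_points": t.n_points}
    return seasons, out


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write the result bundle to ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``.  Any stage failure raises :class:`PipelineError`
    naming the stage; an ``INCOMPLETE`` marker is left in the output
    directory in that case.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    try:
        summary = _run(cfg, out_dir)
    except Exception:
        raise
    marker.unlink()
    return summary


def _run(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    strandings, detections, incidents, issues = _acquire(cfg)

    included = data_io.apply_stranding_exclusions(strandings)
    binned, bin_issues = data_io.assign_bins(included, cfg.start_year,
                                             cfg.width_years)
    agg = data_io.aggregate_counts(binned)

    densities, phen = _phenology(cfg, strandings, detections, incidents)
    demo = _demographics(cfg, included)
    seasons, season = _season(cfg, binned)

    counts_rows = [{"bin": b, "label": bin_label(b, cfg.start_year, cfg.width_years),
                    "shark": s, "nonshark": ns,
                    "quotient": agg.quotient[b], "fraction": agg.fraction[b]}
                   for b, (s, ns) in sorted(agg.bin_totals.items())]
    pd.DataFrame(counts_rows).to_csv(out_dir / "counts.csv", index=False)
    pd.DataFrame(season["bins"]).to_csv(out_dir / "seasons.csv", index=False)
    for name, dens in densities.items():
        phenology.export_density(dens, out_dir / f"density_{name}.csv")

    summary = {
        "seed": cfg.seed,
        "n_strandings": len(strandings),
        "n_included": len(included),
        "n_excluded": len(strandings) - len(included),
        "n_row_issues": len(issues) + len(bin_issues),
        "counts": counts_rows,
        "quotients": {bin_label(b, cfg.start_year, cfg.width_years):
                      agg.quotient[b] for b in sorted(agg.bin_totals)},
        "phenology": phen,
        "demographics": demo,
        "season": season,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")

    lines = [f"strandphen run (seed={cfg.seed})",
             f"numpy={np.__version__} pandas={pd.__version__}",
             f"stage seeds: " + ", ".join(
                 f"{s}={stage_seed(cfg.seed, s)}"
                 for s in ("synthetic", "bootstrap", "perturbation")),
             "decisions in effect:"]
    lines += [f"  - {k}: {v}" for k, v in DIALECT.items()]
    lines += [f"row issues: {len(issues) + len(bin_issues)}"]
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")
    return summary


# ---------------------------------------------------------------------------
# configuration loading (structured-text configs for the CLI)
# ---------------------------------------------------------------------------

def load_run_config(doc: Mapping[str, Any], seed: int | None = None,
                    out_dir: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    syn = None
    if "synthetic" in doc:
        s = dict(doc["synthetic"] or {})
        if s.pop("published_scale", False):
            syn = published_scale_config(seed=int(s.pop("seed", 0)), **s)
        else:
            cells = {tuple(json.loads(k) if k.startswith("[") else k.split("|")): v
                     for k, v in (s.pop("cell_counts", {}) or {}).items()}
            cells = {(int(b), sex, mat, cause): int(n)
                     for (b, sex, mat, cause), n in cells.items()}
            centers = {int(k): float(v)
                       for k, v in (s.pop("season_center", {}) or {}).items()}
            widths = {int(k): float(v)
                      for k, v in (s.pop("season_width80", {}) or {}).items()}
            syn = SyntheticConfig(seed=int(s.pop("seed", 0)), cell_counts=cells,
                                  season_center=centers, season_width80=widths,
                                  **{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in s.items()})
    boot = BootstrapConfig(**doc["bootstrap"]) if "bootstrap" in doc else None
    pert = PerturbationConfig(**doc["perturbation"]) if "perturbation" in doc else None
    scheme = doc.get("bin_scheme", {})
    return RunConfig(
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        out_dir=out_dir or doc.get("out", "run_output"),
        inputs=doc.get("inputs"),
        synthetic=syn,
        column_maps=doc.get("column_maps", {}),
        start_year=int(scheme.get("start_year", 1997)),
        width_years=int(scheme.get("width_years", 3)),
        bandwidth=doc.get("bandwidth", "auto"),
        bootstrap=boot,
        perturbation=pert,
    )
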