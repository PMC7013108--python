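"""End-to-end orchestration: simulate -> networks -> phenotype -> assays -> stats.

A run is described by one YAML/dict configuration with per-stage sections
(unknown keys are rejected so silent typos cannot change an analysis).
Each stage writes its artifacts under the output directory and contributes
counters to a single JSON report; given the same seed and configuration
the report and every artifact are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import (
    DETECTION_LIMITS,
    normalize_expression,
    qc_replicates,
    screen_outliers,
)
from .colocation import daily_networks, read_events, reconstruct_intervals
from .phenotype import classify, degree_distribution, relaxed_rank_selection
from .rankstats import raov_table, spearman
from .simulate import SimConfig, simulate_assays, simulate_tracking

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


_SIM_SCALAR_FIELDS = {
    f.name
    for f in dataclasses.fields(SimConfig)
    if f.name not in {"effect_table", "assay_cv", "qpcr_table", "qpcr_regions"}
}


def _check_keys(section: str, given: dict, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"config section {section!r} has unknown keys: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``simulate`` holds overrides for :class:`~greganet.simulate.SimConfig`
    scalar fields; the remaining sections hold the stage parameters the
    field protocol leaves open (window anchor, overlap threshold,
    consistency rule, outlier fold threshold, test level).
    """

    seed: int = 0
    outdir: str = "greganet_run"
    simulate: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)
    assays: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    _DEFAULTS = {
        "simulate": {"enabled": True},
        "networks": {"window_anchor": "00:00", "min_overlap": 1.0,
                     "max_residence_hours": 12.0, "events": None},
        "phenotype": {"enabled": True, "n_days": 5, "n_required": 3,
                      "relaxed_k": 7, "pooling": "animal-day", "score_days": "last"},
        "assays": {"enabled": True, "fold_threshold": 10.0, "limits": None},
        "stats": {"enabled": True, "alpha": 0.05, "drop_outliers": "both"},
    }

    def __post_init__(self):
        _check_keys("simulate", self.simulate, _SIM_SCALAR_FIELDS | {"enabled"})
        for name in ("networks", "phenotype", "assays", "stats"):
            section = getattr(self, name)
            _check_keys(name, section, set(self._DEFAULTS[name]))
            setattr(self, name, {**self._DEFAULTS[name], **section})
        self.simulate = {"enabled": True, **self.simulate}
        if self.stats["drop_outliers"] not in {"both", "never", "always"}:
            raise ValueError("stats.drop_outliers must be 'both', 'never' or 'always'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        _check_keys("<root>", d, {f.name for f in dataclasses.fields(cls)})
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("run config must be a YAML mapping")
        return cls.from_dict(data)

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": dict(self.simulate),
            "networks": dict(self.networks),
            "phenotype": dict(self.phenotype),
            "assays": dict(self.assays),
            "stats": dict(self.stats),
        }


def _write_json(path: Path, obj: dict):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report (also written
    to ``<outdir>/report.json`` with a plain-text summary alongside)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.echo(),
        "stages": {},
    }

    # -- simulate ----------------------------------------------------------
    sim_cfg = None
    truth = None
    if config.simulate["enabled"]:
        overrides = {k: v for k, v in config.simulate.items() if k != "enabled"}
        overrides.setdefault("seed", config.seed)
        try:
            sim_cfg = SimConfig(**overrides)
            events, truth = simulate_tracking(sim_cfg)
        except ValueError as exc:
            raise StageError("simulate", str(exc)) from exc
        ev = events.copy()
        ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        ev.to_csv(outdir / "events.csv", index=False)
        truth.population.to_csv(outdir / "metadata.csv", index=False)
        sex_map = dict(zip(truth.population["tag_id"], truth.population["sex"]))
        report["stages"]["simulate"] = {
            "n_events": int(len(events)),
            "n_visits": int(len(truth.visits)),
            "n_animals": int(truth.population.shape[0]),
        }
    else:
        path = config.networks["events"]
        if not path:
            raise StageError("networks", "simulation disabled and no events file given")
        log = read_events(path)
        events = log.events
        sex_map = {}
        report["stages"]["read_events"] = {
            "n_events": int(len(events)),
            "anomalies": dict(log.anomalies),
        }

    # -- networks ----------------------------------------------------------
    try:
        intervals, anomalies = reconstruct_intervals(
            events, pd.Timedelta(hours=config.networks["max_residence_hours"])
        )
        nets, degrees = daily_networks(
            intervals,
            anchor=config.networks["window_anchor"],
            min_overlap=config.networks["min_overlap"],
        )
    except (ValueError, KeyError) as exc:
        raise StageError("networks", str(exc)) from exc
    iv = intervals.copy()
    for col in ("t_start", "t_end"):
        iv[col] = iv[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    iv.to_csv(outdir / "intervals.csv", index=False)
    edges = pd.concat(
        [net.edges.assign(day=net.window[0].date().isoformat()) for net in nets],
        ignore_index=True,
    )[["day", "a", "b", "overlap_s", "boxes"]] if nets else pd.DataFrame(
        columns=["day", "a", "b", "overlap_s", "boxes"]
    )
    edges.to_csv(outdir / "edges.csv", index=False)
    degrees.to_csv(outdir / "degrees.csv", index=False)
    report["stages"]["networks"] = {
        "n_intervals": int(len(intervals)),
        "n_windows": len(nets),
        "n_edges_total": int(len(edges)),
        "anomalies": dict(anomalies),
    }

    if not config.phenotype["enabled"]:
        _finalise(outdir, report)
        return report

    # -- phenotype ---------------------------------------------------------
    try:
        days = sorted(degrees["day"].unique())[: config.phenotype["n_days"]]
        dist = degree_distribution(degrees, days=days, pooling=config.phenotype["pooling"])
        assigned = classify(
            degrees[degrees["day"].isin(days)],
            dist,
            n_required=config.phenotype["n_required"],
            score_days=config.phenotype["score_days"],
            sex=sex_map,
        )
        k = config.phenotype["relaxed_k"]
        if k:
            cohorts = []
            for s in ("F", "M"):
                for lab in ("high", "low"):
                    cohorts.append(
                        relaxed_rank_selection(
                            degrees[degrees["day"].isin(days)], dist, lab, int(k),
                            sex=sex_map, restrict_sex=s or None,
                            n_required=config.phenotype["n_required"],
                            score_days=config.phenotype["score_days"],
                        )
                    )
            sampled = pd.concat(cohorts, ignore_index=True)
        else:
            sampled = assigned[assigned["label"] != "unclassified"].copy()
            sampled["relaxed"] = False
    except ValueError as exc:
        raise StageError("phenotype", str(exc)) from exc
    assigned.to_csv(outdir / "phenotypes_strict.csv", index=False)
    sampled.to_csv(outdir / "phenotypes_sampled.csv", index=False)
    _write_json(outdir / "degree_distribution.json", dist.to_dict())
    report["stages"]["phenotype"] = {
        "distribution": dist.to_dict(),
        "n_high_strict": int((assigned["label"] == "high").sum()),
        "n_low_strict": int((assigned["label"] == "low").sum()),
        "n_unclassified": int((assigned["label"] == "unclassified").sum()),
        "n_sampled": int(len(sampled)),
        "n_relaxed": int(sampled["relaxed"].sum()) if "relaxed" in sampled else 0,
    }

    if not config.assays["enabled"]:
        _finalise(outdir, report)
        return report

    # -- assays ------------------------------------------------------------
    try:
        if sim_cfg is None:
            raise StageError("assays", "assay stage currently requires simulation input")
        tables = simulate_assays(
            sim_cfg, sampled[["tag_id", "sex", "label"]].drop_duplicates("tag_id")
        )
        limits = config.assays["limits"] or DETECTION_LIMITS
        serum_qc = qc_replicates(tables.serum, limits)
        hair_qc = qc_replicates(tables.hair, limits)
        expression = normalize_expression(tables.qpcr)
    except StageError:
        raise
    except ValueError as exc:
        raise StageError("assays", str(exc)) from exc
    measurements = pd.concat(
        [serum_qc.assign(assay="serum"), hair_qc.assign(assay="hair")], ignore_index=True
    )
    flags = {}
    for analyte, grp in measurements.groupby("analyte"):
        if len(grp) >= 3:
            flagged = screen_outliers(grp["mean"].to_numpy(), config.assays["fold_threshold"])
            flags[analyte] = grp.loc[flagged, "sample_id"].tolist()
    measurements.to_csv(outdir / "measurements.csv", index=False)
    expression.to_csv(outdir / "expression.csv", index=False)
    tables.sampling.to_csv(outdir / "sampling.csv", index=False)
    qc_report = {
        "cv_by_analyte": {
            a: round(float(g["cv_pct"].mean()), 4)
            for a, g in measurements.groupby("analyte")
        },
        "below_detection_counts": {
            a: int(g["below_detection"].sum())
            for a, g in measurements.groupby("analyte")
        },
        "outlier_flags": flags,
        "missing_housekeeping": int((expression["flag"] == "missing_housekeeping").sum()),
    }
    _write_json(outdir / "qc.json", qc_report)
    report["stages"]["assays"] = {
        "n_measurements": int(len(measurements)),
        "n_expression_records": int(len(expression)),
        "qc": qc_report,
    }

    if not config.stats["enabled"]:
        _finalise(outdir, report)
        return report

    # -- stats -------------------------------------------------------------
    try:
        anova, correlations = _stats_stage(config, measurements, expression, tables, flags)
    except ValueError as exc:
        raise StageError("stats", str(exc)) from exc
    anova.to_csv(outdir / "anova.csv", index=False)
    _write_json(outdir / "correlations.json", correlations)
    alpha = config.stats["alpha"]
    report["stages"]["stats"] = {
        "anova": anova.to_dict(orient="records"),
        "significant_terms": anova.loc[anova["p"] < alpha, ["response", "dataset", "term"]]
        .agg("|".join, axis=1)
        .tolist(),
        "correlations": correlations,
    }
    _finalise(outdir, report)
    return report


def _stats_stage(config, measurements, expression, tables, flags):
    cohort = tables.sampling.set_index("tag_id")
    rows = []

    def _run(response_name, dataset, frame, value_col):
        merged = frame.join(cohort[["sex", "label"]], how="inner")
        if merged[value_col].notna().sum() < 8:
            return
        tab = raov_table(
            merged[value_col].to_numpy(),
            merged["sex"].to_numpy(),
            merged["label"].to_numpy(),
            term_names=("sex", "phenotype"),
        )
        for rec in tab.to_dict(orient="records"):
            rows.append({"response": response_name, "dataset": dataset, **rec})

    drop_mode = config.stats["drop_outliers"]
    for analyte, grp in measurements.groupby("analyte"):
        frame = grp.set_index("sample_id")[["mean"]]
        if drop_mode in {"both", "never"}:
            _run(analyte, "all", frame, "mean")
        flagged = flags.get(analyte, [])
        if drop_mode in {"both", "always"} and flagged:
            _run(analyte, "outliers_removed", frame.drop(index=flagged, errors="ignore"), "mean")

    for (gene, region), grp in expression.groupby(["gene", "region"]):
        frame = grp.set_index("sample_id")
        col = "R0" if frame["R0_norm"].isna().all() else "R0_norm"
        _run(f"qpcr:{gene}", region, frame[[col]], col)

    anova = pd.DataFrame(rows, columns=["response", "dataset", "term", "F", "df1", "df2", "p"])

    correlations = {}
    cort = measurements[measurements["analyte"] == "corticosterone_serum"]
    if not cort.empty:
        merged = cort.set_index("sample_id").join(
            cohort[["time_to_euthanasia_min"]], how="inner"
        ).dropna(subset=["mean", "time_to_euthanasia_min"])
        if len(merged) >= 4:
            rho, p, df = spearman(merged["mean"], merged["time_to_euthanasia_min"])
            correlations["corticosterone_serum~time_to_euthanasia"] = {
                "rho": round(rho, 6), "p": round(p, 6), "df": df,
            }
    return anova, correlations


def _finalise(outdir: Path, report: dict):
    _write_json(outdir / "report.json", report)
    lines = [f"greganet {report['version']} run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            if isinstance(v, (int, float, str)):
                lines.append(f"  {k}: {v}")
        lines.append("")
    if "stats" in report["stages"]:
        lines.append("significant terms (p < alpha):")
        for t in report["stages"]["stats"]["significant_terms"]:
            lines.append(f"  {t}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
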