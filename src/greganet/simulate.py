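"""Synthetic barn: RFID event logs, metadata and assay tables with known truth.

Emulates a free-living house-mouse population tracked by antenna-fitted
nest boxes.  Each animal carries a latent sociability class (``high`` or
``low``): high-class animals make more nest-box visits per day and spread
them over more boxes (a flatter Dirichlet box preference), which is the
mechanism that separates their daily co-location degree from low-class
animals.  Visits follow an inhomogeneous Poisson process with a nocturnal
activity peak.  Each completed visit emits an ``in`` and an ``out``
antenna read, each independently dropped with probability ``miss_prob``
to exercise the interval-reconstruction heuristics downstream.

Assay tables (serum cytokines, hair steroids, qPCR wells) are generated
from a linear sex x phenotype effect model with Gaussian noise, truncated
at zero, plus replicate-level intra-assay noise; qPCR cycle thresholds
come from the log-concentration model ``Ct = -ln(c)/ln(1+E) + noise`` so
the efficiency-corrected R0 pipeline recovers planted concentration
ratios exactly in the noise-free limit.

Everything is driven by one integer seed; identical configurations give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "SimConfig",
    "GroundTruth",
    "AssayTables",
    "simulate_tracking",
    "simulate_assays",
    "events_from_visits",
    "truth_from_visits",
    "write_simulation",
    "DEFAULT_EFFECTS",
    "DEFAULT_ASSAY_CV",
    "DEFAULT_QPCR",
]


@dataclass(frozen=True)
class EffectSpec:
    """Additive sex x phenotype effect model for one analyte.

    value = baseline + sex_effect*1[male] + phenotype_effect*1[high] + N(0, noise_sd),
    truncated at zero (concentrations are non-negative).
    """

    baseline: float
    sex_effect: float
    phenotype_effect: float
    noise_sd: float
    assay: str = "serum"  # 'serum' | 'hair'


#: Default planted effects, loosely shaped like the study system: a male and
#: high-gregariousness elevation in serum TNF-a, sex effects on steroids, a
#: phenotype effect on progesterone, and null cytokines otherwise.
DEFAULT_EFFECTS: dict[str, EffectSpec] = {
    "TNF-a": EffectSpec(6.0, 5.0, 5.0, 2.5, "serum"),
    "IFN-g": EffectSpec(14.0, 0.0, 0.0, 5.0, "serum"),
    "IL-1b": EffectSpec(4.0, 0.0, 0.0, 1.5, "serum"),
    "corticosterone_serum": EffectSpec(260.0, -80.0, 0.0, 70.0, "serum"),
    "corticosterone_hair": EffectSpec(3.5, 0.0, 0.9, 1.2, "hair"),
    "testosterone_hair": EffectSpec(2.5, 3.0, 0.9, 1.1, "hair"),
    "progesterone_hair": EffectSpec(14.0, -7.0, 6.0, 3.0, "hair"),
}

#: Intra-assay duplicate %CV per analyte (multiplicative replicate noise).
DEFAULT_ASSAY_CV: dict[str, float] = {
    "TNF-a": 9.0,
    "IFN-g": 11.0,
    "IL-1b": 8.0,
    "corticosterone_serum": 6.0,
    "corticosterone_hair": 6.0,
    "testosterone_hair": 6.0,
    "progesterone_hair": 6.0,
}

#: qPCR targets: relative expression effect model and per-gene efficiency.
DEFAULT_QPCR: dict[str, tuple[EffectSpec, float]] = {
    "Actb": (EffectSpec(1.0, 0.0, 0.0, 0.0, "qpcr"), 0.95),
    "TNF-a": (EffectSpec(1.0, 0.0, 0.0, 0.12, "qpcr"), 0.90),
    "IFN-g": (EffectSpec(0.8, 0.0, 0.0, 0.10, "qpcr"), 0.85),
    "IL-1b": (EffectSpec(1.2, 0.0, 0.0, 0.12, "qpcr"), 0.92),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the barn population under study
    (40 nest boxes, winter tracking, a population mean degree in the
    mid-20s with SD near 9 partners/day)."""

    n_animals: int = 60
    n_boxes: int = 40
    n_days: int = 5
    sex_ratio: float = 0.5  # fraction female
    sociability_high_fraction: float = 0.5
    visit_rate_high: float = 40.0  # visits/day
    visit_rate_low: float = 16.0
    mean_visit_duration: float = 45.0  # minutes
    box_preference_concentration: float = 0.3  # Dirichlet alpha, low class
    high_box_flatness: float = 10.0  # alpha multiplier for high class
    nocturnal_amplitude: float = 0.8  # 0 = uniform activity over the day
    miss_prob: float = 0.02
    seed: int = 0
    start: str = "2019-12-20"
    min_overlap: float = 1.0  # seconds, for ground-truth edges
    effect_table: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    assay_cv: dict = field(default_factory=lambda: dict(DEFAULT_ASSAY_CV))
    qpcr_table: dict = field(default_factory=lambda: dict(DEFAULT_QPCR))
    qpcr_regions: tuple = ("hypothalamus", "cortex")
    qpcr_well_noise_sd: float = 0.15  # cycles
    rna_scale_log2_sd: float = 0.5  # per-sample input-RNA variation
    n_replicates: int = 2
    tte_mean: float = 9.7  # minutes from entering the sector to euthanasia
    tte_sd: float = 4.0
    cort_tte_slope: float = 12.0  # serum corticosterone rise per minute held

    def __post_init__(self):
        positive = [
            "n_animals", "n_boxes", "n_days", "visit_rate_high", "visit_rate_low",
            "mean_visit_duration", "box_preference_concentration",
            "high_box_flatness", "min_overlap", "n_replicates", "tte_mean", "tte_sd",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be strictly positive")
        for name in ["sex_ratio", "sociability_high_fraction", "miss_prob"]:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"SimConfig.{name} must lie in [0, 1]")
        if not 0.0 <= self.nocturnal_amplitude < 1.0:
            raise ValueError("SimConfig.nocturnal_amplitude must lie in [0, 1)")
        for analyte, spec in self.effect_table.items():
            if spec.assay not in {"serum", "hair"}:
                raise ValueError(
                    f"SimConfig.effect_table[{analyte!r}]: unknown assay kind {spec.assay!r}"
                )
        for analyte in self.assay_cv:
            if analyte not in self.effect_table:
                raise ValueError(
                    f"SimConfig.assay_cv names unknown analyte {analyte!r}"
                )


@dataclass
class GroundTruth:
    """What the generator planted, before any antenna read was dropped."""

    population: pd.DataFrame  # tag_id, sex, true_class
    visits: pd.DataFrame  # tag_id, box_id, t_start, t_end
    daily_edges: dict  # day iso-date -> set of frozenset pairs
    daily_degrees: pd.DataFrame  # tag_id, day, degree


@dataclass
class AssayTables:
    """Simulated wet-lab tables plus the planted group means."""

    serum: pd.DataFrame
    hair: pd.DataFrame
    qpcr: pd.DataFrame
    sampling: pd.DataFrame  # tag_id, sex, label, time_to_euthanasia_min
    group_means: dict


def _tag(i: int) -> str:
    return f"T{i + 1:03d}"


def _box(i: int) -> str:
    return f"B{i + 1:02d}"


def _population(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_animals
    tags = [_tag(i) for i in range(n)]
    n_f = int(round(n * config.sex_ratio))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    # stratify the planted class within sex so every sex x class cell exists
    cls = np.empty(n, dtype=object)
    for s in ("F", "M"):
        idx = np.flatnonzero(sex == s)
        n_high = int(round(idx.size * config.sociability_high_fraction))
        chosen = rng.permutation(idx)[:n_high]
        cls[idx] = "low"
        cls[chosen] = "high"
    return pd.DataFrame({"tag_id": tags, "sex": sex, "true_class": cls})


def _sample_visit_times(
    rng: np.random.Generator, rate: float, n_days: int, amplitude: float
) -> np.ndarray:
    """Inhomogeneous Poisson start times (hours from t0) with a 02:00 peak."""
    n = rng.poisson(rate * n_days)
    out = np.empty(0)
    while out.size < n:
        t = rng.uniform(0.0, n_days * 24.0, size=2 * (n - out.size) + 8)
        intensity = 1.0 + amplitude * np.cos(2 * np.pi * (t % 24.0 - 2.0) / 24.0)
        keep = rng.uniform(0.0, 1.0 + amplitude, size=t.size) < intensity
        out = np.concatenate([out, t[keep]])
    return np.sort(out[:n])


def _generate_visits(
    config: SimConfig, population: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    t0 = pd.Timestamp(config.start)
    horizon = config.n_days * 24.0
    frames = []
    box_names = np.array([_box(i) for i in range(config.n_boxes)])
    for tag, cls in zip(population["tag_id"], population["true_class"]):
        high = cls == "high"
        rate = config.visit_rate_high if high else config.visit_rate_low
        alpha = config.box_preference_concentration * (
            config.high_box_flatness if high else 1.0
        )
        prefs = rng.dirichlet(np.full(config.n_boxes, alpha))
        starts = _sample_visit_times(rng, rate, config.n_days, config.nocturnal_amplitude)
        durations = rng.exponential(config.mean_visit_duration / 60.0, size=starts.size)
        boxes = rng.choice(config.n_boxes, size=starts.size, p=prefs)
        ends = starts + durations
        # an animal is in at most one box at once: cap at the next entry
        if starts.size > 1:
            ends[:-1] = np.minimum(ends[:-1], starts[1:] - 1.0 / 3600.0)
        ends = np.minimum(ends, horizon)
        keep = ends - starts >= 10.0 / 3600.0  # drop sub-10 s stubs
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "box_id": box_names[boxes[keep]],
                    "t_start": t0
                    + pd.to_timedelta(np.round(starts[keep] * 3600.0, 3), unit="s"),
                    "t_end": t0
                    + pd.to_timedelta(np.round(ends[keep] * 3600.0, 3), unit="s"),
                }
            )
        )
    visits = pd.concat(frames, ignore_index=True)
    return visits.sort_values(["t_start", "tag_id"], ignore_index=True)


def truth_from_visits(visits: pd.DataFrame, min_overlap: float = 1.0) -> tuple[dict, pd.DataFrame]:
    """Ground-truth daily edge sets and degrees from the true visit spans.

    Brute force by construction (all pairwise intersections per box per
    midnight-anchored day), independent of the sweep-line used by the
    co-location module, so it doubles as an oracle.  Visits crossing
    midnight contribute to both days.
    """
    if visits.empty:
        return {}, pd.DataFrame(columns=["tag_id", "day", "degree"])
    d0 = visits["t_start"].min().normalize()
    d1 = visits["t_end"].max()
    daily_edges: dict = {}
    deg_rows = []
    day = d0
    while day <= d1:
        w0, w1 = day, day + pd.Timedelta(days=1)
        t0 = visits["t_start"].clip(lower=w0)
        t1 = visits["t_end"].clip(upper=w1)
        keep = t0 < t1
        sub = pd.DataFrame(
            {"tag_id": visits.loc[keep, "tag_id"], "box_id": visits.loc[keep, "box_id"],
             "t0": t0[keep], "t1": t1[keep]}
        )
        edges: set = set()
        if not sub.empty:
            for _, grp in sub.groupby("box_id"):
                tg = grp["tag_id"].to_numpy()
                a0 = grp["t0"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
                a1 = grp["t1"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
                if len(grp) < 2:
                    continue
                ii, jj = np.triu_indices(len(grp), k=1)
                ov_ns = np.minimum(a1[ii], a1[jj]) - np.maximum(a0[ii], a0[jj])
                hit = (ov_ns >= min_overlap * 1e9) & (tg[ii] != tg[jj])
                for i, j in zip(ii[hit], jj[hit]):
                    edges.add(frozenset((tg[i], tg[j])))
            key = w0.date().isoformat()
            daily_edges[key] = edges
            counts: dict = {t: 0 for t in sub["tag_id"].unique()}
            for e in edges:
                for t in e:
                    counts[t] += 1
            for t in sorted(counts):
                deg_rows.append((t, key, counts[t]))
        day = w1
    degrees = pd.DataFrame(deg_rows, columns=["tag_id", "day", "degree"])
    return daily_edges, degrees


def events_from_visits(
    visits: pd.DataFrame, miss_prob: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit antenna in/out reads for each visit, dropping reads independently
    with probability ``miss_prob``."""
    n = len(visits)
    keep_in = rng.uniform(size=n) >= miss_prob
    keep_out = rng.uniform(size=n) >= miss_prob
    frames = []
    for keep, tcol, direction, reader in (
        (keep_in, "t_start", "in", "A1"),
        (keep_out, "t_end", "out", "A2"),
    ):
        sub = visits.loc[keep, ["tag_id", "box_id"]].copy()
        sub["timestamp"] = visits.loc[keep, tcol]
        sub["reader_id"] = sub["box_id"] + ":" + reader
        sub["direction"] = direction
        frames.append(sub)
    events = pd.concat(frames, ignore_index=True)
    events = events[["timestamp", "tag_id", "box_id", "reader_id", "direction"]]
    return events.sort_values(["timestamp", "tag_id", "direction"], ignore_index=True)


def simulate_tracking(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the antenna event stream and its ground truth."""
    rng = np.random.default_rng(config.seed)
    population = _population(config, rng)
    visits = _generate_visits(config, population, rng)
    daily_edges, daily_degrees = truth_from_visits(visits, config.min_overlap)
    events = events_from_visits(visits, config.miss_prob, rng)
    return events, GroundTruth(population, visits, daily_edges, daily_degrees)


def _true_value(spec: EffectSpec, male: bool, high: bool) -> float:
    return (
        spec.baseline
        + spec.sex_effect * (1.0 if male else 0.0)
        + spec.phenotype_effect * (1.0 if high else 0.0)
    )


def simulate_assays(
    config: SimConfig,
    phenotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> AssayTables:
    """Generate serum, hair and qPCR tables for a labelled cohort.

    ``phenotypes`` needs columns ``tag_id, sex, label`` with sex in {F, M}
    and label in {high, low}; effects are keyed to these labels.  Serum
    corticosterone additionally rises with the simulated time from
    disturbance to euthanasia (``cort_tte_slope``), reproducing the
    handling-stress correlation the Spearman stage measures.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    for col in ("tag_id", "sex", "label"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotypes table missing column {col!r}")
    bad = set(phenotypes["label"]) - {"high", "low"}
    if bad:
        raise ValueError(f"phenotypes contain non high/low labels: {sorted(bad)}")
    bad = set(phenotypes["sex"]) - {"F", "M"}
    if bad:
        raise ValueError(f"phenotypes contain unknown sex codes: {sorted(bad)}")

    cohort = phenotypes.sort_values("tag_id", ignore_index=True)
    male = (cohort["sex"] == "M").to_numpy()
    high = (cohort["label"] == "high").to_numpy()
    n = len(cohort)
    tte = np.clip(rng.normal(config.tte_mean, config.tte_sd, size=n), 1.0, None)

    serum_rows, hair_rows = [], []
    group_means: dict = {}
    for analyte, spec in config.effect_table.items():
        cv = config.assay_cv.get(analyte, 0.0)
        truth = np.array([_true_value(spec, m, h) for m, h in zip(male, high)])
        truth = truth + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else truth
        if analyte == "corticosterone_serum":
            truth = truth + config.cort_tte_slope * (tte - config.tte_mean)
        truth = np.clip(truth, 0.0, None)
        group_means[analyte] = {
            f"{s}/{l}": _true_value(spec, s == "M", l == "high")
            for s in ("F", "M")
            for l in ("high", "low")
        }
        rows = serum_rows if spec.assay == "serum" else hair_rows
        for i, tag in enumerate(cohort["tag_id"]):
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, cv / 100.0) if cv > 0 else 0.0
                rows.append((tag, analyte, rep, max(truth[i] * (1.0 + noise), 0.0)))

    serum = pd.DataFrame(serum_rows, columns=["sample_id", "analyte", "replicate", "value"])
    hair = pd.DataFrame(hair_rows, columns=["sample_id", "analyte", "replicate", "value"])

    qpcr_rows = []
    log2_scale = rng.normal(0.0, config.rna_scale_log2_sd, size=(n, len(config.qpcr_regions)))
    for g, (spec, eff) in config.qpcr_table.items():
        truth_expr = np.array([_true_value(spec, m, h) for m, h in zip(male, high)])
        group_means[f"qpcr:{g}"] = {
            f"{s}/{l}": _true_value(spec, s == "M", l == "high")
            for s in ("F", "M")
            for l in ("high", "low")
        }
        for r_idx, region in enumerate(config.qpcr_regions):
            expr = truth_expr.copy()
            if spec.noise_sd > 0:
                expr = expr + rng.normal(0.0, spec.noise_sd, size=n)
            expr = np.clip(expr, 1e-6, None)
            # concentration in absolute units: relative expression times the
            # per-sample input-RNA amount (median ~2^-12 of a unit template)
            conc = expr * np.exp2(log2_scale[:, r_idx] - 12.0)
            ct = -np.log(conc) / np.log1p(eff)
            for i, tag in enumerate(cohort["tag_id"]):
                for _rep in range(1, config.n_replicates + 1):
                    noise = (
                        rng.normal(0.0, config.qpcr_well_noise_sd)
                        if config.qpcr_well_noise_sd > 0
                        else 0.0
                    )
                    qpcr_rows.append((tag, region, g, max(ct[i] + noise, 0.01), eff))
    qpcr = pd.DataFrame(qpcr_rows, columns=["sample_id", "region", "gene", "Ct", "E"])

    sampling = cohort.assign(time_to_euthanasia_min=np.round(tte, 2))
    return AssayTables(serum, hair, qpcr, sampling, group_means)


def write_simulation(config: SimConfig, outdir) -> dict[str, Path]:
    """Run the full generator and write plain-text artifacts.

    Writes ``events.csv``, ``metadata.csv``, ``serum.csv``, ``hair.csv``,
    ``qpcr.csv``, ``sampling.csv`` and ``truth.json`` (assays are generated
    for the whole population keyed to the *true* classes).  Returns the
    path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events, truth = simulate_tracking(config)
    assays = simulate_assays(
        config,
        truth.population.rename(columns={"true_class": "label"}),
    )
    paths = {}

    def _write(name: str, df: pd.DataFrame, **kwargs):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, **kwargs)
        paths[name] = p

    ev = events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    _write("events", ev)
    _write("metadata", truth.population)
    _write("serum", assays.serum)
    _write("hair", assays.hair)
    _write("qpcr", assays.qpcr)
    _write("sampling", assays.sampling)

    truth_json = {
        "config": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, dict) and not isinstance(v, tuple)
        },
        "classes": dict(zip(truth.population["tag_id"], truth.population["true_class"])),
        "daily_edges": {
            day: sorted(sorted(pair) for pair in edges)
            for day, edges in truth.daily_edges.items()
        },
        "daily_degrees": truth.daily_degrees.to_dict(orient="list"),
        "analyte_group_means": assays.group_means,
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    paths["truth"] = p
    return paths


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced (validated)."""
    return replace(config, **kwargs)
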