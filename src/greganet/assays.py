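"""qPCR expression normalization and immunoassay / hormone-table QC.

Covers the wet-lab side of the analysis:

* efficiency-corrected qPCR quantification, ``R0 = (1+E)^(-Ct)`` — the
  relative starting-template concentration given the cycle threshold
  ``Ct`` and per-cycle amplification efficiency ``E`` (fraction in
  (0, 1]; E=1 is perfect doubling) — normalized per sample and brain
  region to the housekeeping gene beta-Actin;
* duplicate QC for multiplex / ELISA measurements: replicate mean,
  intra-assay %CV, and detection-limit flagging;
* the fold-over-mean outlier screen used before the group statistics,
  plus Tukey-style boxplot summaries with configurable whisker factors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING_GENE",
    "DETECTION_LIMITS",
    "compute_R0",
    "normalize_expression",
    "qc_replicates",
    "screen_outliers",
    "boxplot_stats",
]

HOUSEKEEPING_GENE = "Actb"

#: Assay detection limits, pg/mL (serum multiplex panel and corticosterone ELISA).
DETECTION_LIMITS = {
    "IFN-g": 3.05,
    "IL-1b": 0.81,
    "TNF-a": 4.02,
    "corticosterone_serum": 16.9,
}


def compute_R0(ct, efficiency):
    """Efficiency-corrected relative start concentration, ``(1+E)^(-Ct)``.

    Accepts scalars or arrays.  ``E`` must lie in (0, 1]; values in
    (1, 100] are taken to be percentages and converted with a warning.
    ``Ct`` must be non-negative (Ct = 0 gives R0 = 1).
    """
    ct = np.asarray(ct, dtype=float)
    e = np.asarray(efficiency, dtype=float)
    if np.any(e > 1.0):
        if np.any(e > 100.0):
            raise ValueError("amplification efficiency out of range")
        warnings.warn("efficiency > 1 interpreted as percent; dividing by 100",
                      stacklevel=2)
        e = np.where(e > 1.0, e / 100.0, e)
    if np.any(e <= 0.0):
        raise ValueError("amplification efficiency must be positive")
    if np.any(ct < 0.0):
        raise ValueError("Ct must be non-negative")
    out = np.power(1.0 + e, -ct)
    return out if out.ndim else float(out)


def normalize_expression(
    wells: pd.DataFrame,
    housekeeping: str = HOUSEKEEPING_GENE,
) -> pd.DataFrame:
    """Per-sample, per-region expression normalized to the housekeeping gene.

    ``wells`` needs columns ``sample_id, region, gene, Ct, E``.  Duplicate
    wells of the same (sample, region, gene) are collapsed by mean Ct
    (within-gene E is constant by construction; if not, mean E is used).
    Output rows carry ``R0`` and ``R0_norm = R0 / R0(housekeeping)``;
    samples lacking a housekeeping well in that region keep ``R0`` but get
    ``R0_norm = NaN`` and ``flag = 'missing_housekeeping'``.  Housekeeping
    rows themselves report raw ``R0`` with ``R0_norm = NaN``.
    """
    required = {"sample_id", "region", "gene", "Ct", "E"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    collapsed = (
        wells.groupby(["sample_id", "region", "gene"], as_index=False, sort=True)
        .agg(Ct=("Ct", "mean"), E=("E", "mean"), n_wells=("Ct", "size"))
    )
    collapsed["R0"] = compute_R0(collapsed["Ct"].to_numpy(), collapsed["E"].to_numpy())

    hk = (
        collapsed[collapsed["gene"] == housekeeping]
        .set_index(["sample_id", "region"])["R0"]
    )
    idx = pd.MultiIndex.from_frame(collapsed[["sample_id", "region"]])
    hk_r0 = hk.reindex(idx).to_numpy()
    is_hk = (collapsed["gene"] == housekeeping).to_numpy()
    with np.errstate(invalid="ignore"):
        collapsed["R0_norm"] = np.where(is_hk, np.nan, collapsed["R0"] / hk_r0)
    collapsed["flag"] = np.where(
        ~is_hk & np.isnan(hk_r0), "missing_housekeeping", ""
    )
    return collapsed


def qc_replicates(
    raw: pd.DataFrame,
    limits: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Collapse replicate assay rows into QC'd measurements.

    ``raw`` needs columns ``sample_id, analyte, value`` (a ``replicate``
    column is optional).  Per sample x analyte the output reports the
    replicate mean, the intra-assay %CV (sample SD convention; NaN when
    only one replicate survives) and, where ``limits`` provides a
    detection limit, a ``below_detection`` flag (mean < limit).  Negative
    raw values are rejected with a reason rather than silently dropped;
    below-detection measurements are retained and flagged, not
    substituted.
    """
    required = {"sample_id", "analyte", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    limits = dict(DETECTION_LIMITS if limits is None else limits)

    values = pd.to_numeric(raw["value"], errors="coerce")
    bad = values.isna() | (values < 0)
    rejected = raw.loc[bad].copy()
    if not rejected.empty:
        rejected["reason"] = np.where(
            values[bad].isna(), "non_numeric_value", "negative_concentration"
        )
        warnings.warn(f"rejected {len(rejected)} assay rows", stacklevel=2)
    ok = raw.loc[~bad].assign(value=values[~bad])

    rows = []
    for (sample, analyte), grp in ok.groupby(["sample_id", "analyte"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        mean = float(np.mean(v))
        cv = float(100.0 * np.std(v, ddof=1) / mean) if v.size > 1 and mean > 0 else np.nan
        limit = limits.get(analyte, np.nan)
        rows.append(
            {
                "sample_id": sample,
                "analyte": analyte,
                "n_replicates": int(v.size),
                "mean": mean,
                "cv_pct": cv,
                "detection_limit": limit,
                "below_detection": bool(mean < limit) if np.isfinite(limit) else False,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "analyte", "n_replicates", "mean",
            "cv_pct", "detection_limit", "below_detection",
        ],
    )
    out.attrs["rejected"] = rejected.to_dict(orient="records")
    return out


def screen_outliers(values, fold_threshold: float = 10.0) -> np.ndarray:
    """Flag values at least ``fold_threshold`` times the overall mean.

    The screen targets single extreme observations that dominate a small
    sample; analyses are meant to be reported both with and without the
    flagged points.  Returns a boolean array; requires >= 3 values and a
    positive mean (otherwise the screen is skipped with a warning and
    nothing is flagged).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    mean = v.mean()
    if mean <= 0:
        warnings.warn("non-positive mean; outlier screen skipped", stacklevel=2)
        return np.zeros(v.size, dtype=bool)
    return v / mean >= fold_threshold


def boxplot_stats(
    values,
    upper_whisker: float = 1.5,
    lower_whisker: float = 1.5,
) -> dict:
    """Five-number boxplot summary with whisker-based outliers.

    Quartiles use linear interpolation (type-7).  The upper whisker is the
    largest observation within ``upper_whisker * IQR`` above the 75th
    percentile (the lower mirror uses ``lower_whisker``); points beyond
    the whiskers are reported as outliers.  Both whisker factors are
    parameters because published fence conventions vary.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    hi_fence = q3 + upper_whisker * iqr
    lo_fence = q1 - lower_whisker * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisk_hi = float(inside.max()) if inside.size else float(med)
    whisk_lo = float(inside.min()) if inside.size else float(med)
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": whisk_lo,
        "whisker_high": whisk_hi,
        "outliers": outliers.tolist(),
    }
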