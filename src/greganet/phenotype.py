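"""Population degree distribution and extreme-gregariousness classification.

The social phenotype is defined against the population: pool daily degree
values over a reference span (default five 24 h windows), compute their
mean and standard deviation, and call an animal *high* (resp. *low*)
gregariousness when its daily degree was at least 1 SD above (resp. below)
the population mean on at least three separate days.  Each classified
animal's gregariousness score is its mean degree over three qualifying
days.  When a sex runs out of strictly qualifying animals, the cohort is
filled by rank: the animals whose mean degree most closely approaches the
threshold from the correct side of the population mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegreeDistribution",
    "degree_distribution",
    "classify",
    "relaxed_rank_selection",
    "plot_degree_distribution",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Pooled population degree distribution and its +/-1 SD thresholds."""

    mean: float
    std: float
    n_obs: int
    days_used: tuple = ()
    pooling: str = "animal-day"

    @property
    def high_threshold(self) -> float:
        return self.mean + self.std

    @property
    def low_threshold(self) -> float:
        return self.mean - self.std

    @property
    def degenerate(self) -> bool:
        return self.std == 0.0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "n_obs": self.n_obs,
            "high_threshold": self.high_threshold,
            "low_threshold": self.low_threshold,
            "days_used": list(self.days_used),
            "pooling": self.pooling,
        }


def degree_distribution(
    records: pd.DataFrame,
    days=None,
    pooling: str = "animal-day",
    ddof: int = 1,
) -> DegreeDistribution:
    """Mean +/- SD of the population degree distribution.

    Parameters
    ----------
    records : DataFrame with ``tag_id, day, degree``.
    days : optional subset of days to pool (default: all days present).
    pooling : "animal-day" pools every animal-day value into one
        distribution; "animal-mean" first averages each animal over the
        selected days.
    ddof : 1 for the sample (n-1) standard deviation.
    """
    if days is not None:
        days = list(days)
        records = records[records["day"].isin(days)]
    else:
        days = sorted(records["day"].unique())
    if pooling == "animal-day":
        values = records["degree"].to_numpy(dtype=float)
    elif pooling == "animal-mean":
        values = records.groupby("tag_id")["degree"].mean().to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if values.size < 2:
        raise ValueError("need at least 2 degree observations to form a distribution")
    return DegreeDistribution(
        mean=float(np.mean(values)),
        std=float(np.std(values, ddof=ddof)),
        n_obs=int(values.size),
        days_used=tuple(days),
        pooling=pooling,
    )


def _pick_days(days: list, degrees: list, n: int, score_days: str) -> list:
    order = np.argsort(days, kind="stable")
    ordered = [days[i] for i in order]
    if score_days == "first":
        return ordered[:n]
    if score_days == "last":
        return ordered[-n:]
    if score_days == "all":
        return ordered
    raise ValueError(f"unknown score_days {score_days!r}")


def classify(
    records: pd.DataFrame,
    dist: DegreeDistribution,
    n_required: int = 3,
    score_days: str = "last",
    sex: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Assign high/low/unclassified gregariousness labels.

    ``high`` needs at least ``n_required`` distinct days with degree >=
    ``dist.high_threshold``; ``low`` the mirror image.  The score is the
    mean degree over the ``n_required`` most recent qualifying days (or the
    earliest/all, per ``score_days``).  Animals observed on fewer than
    ``n_required`` days, or qualifying for neither (or pathologically for
    both) side, come back ``unclassified`` with a reason code.

    Returns a DataFrame with ``tag_id, sex, label, score, n_days_observed,
    qualifying_days, reason``; row order is by ``tag_id``, and the result
    is invariant to the order of the input records.
    """
    if dist.degenerate:
        raise ValueError("degenerate degree distribution (std = 0); cannot classify")
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    sex_map = dict(sex) if sex is not None else {}

    rows = []
    for tag, grp in records.groupby("tag_id", sort=True):
        grp = grp.drop_duplicates(subset="day")
        days = list(grp["day"])
        degs = list(grp["degree"].astype(float))
        by_day = dict(zip(days, degs))
        hi_days = [d for d in days if by_day[d] >= dist.high_threshold]
        lo_days = [d for d in days if by_day[d] <= dist.low_threshold]
        label, reason, qual = "unclassified", "", []
        if len(days) < n_required:
            reason = "too_few_days"
        elif len(hi_days) >= n_required and len(lo_days) >= n_required:
            reason = "ambiguous_both_sides"
        elif len(hi_days) >= n_required:
            label, qual = "high", _pick_days(hi_days, degs, n_required, score_days)
        elif len(lo_days) >= n_required:
            label, qual = "low", _pick_days(lo_days, degs, n_required, score_days)
        else:
            reason = "not_consistent"
        score = float(np.mean([by_day[d] for d in qual])) if qual else np.nan
        rows.append(
            {
                "tag_id": tag,
                "sex": sex_map.get(tag, ""),
                "label": label,
                "score": score,
                "n_days_observed": len(days),
                "qualifying_days": ";".join(str(d) for d in qual),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def plot_degree_distribution(records: pd.DataFrame, dist: DegreeDistribution, path=None):
    """Histogram of pooled daily degree values with the +/-1 SD thresholds
    marked as dotted lines; optionally saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(records["degree"], bins=30, color="0.7", edgecolor="0.3")
    for x in (dist.low_threshold, dist.high_threshold):
        ax.axvline(x, linestyle=":", color="k")
    ax.axvline(dist.mean, linestyle="-", color="k", linewidth=0.8)
    ax.set_xlabel("daily degree (partners/day)")
    ax.set_ylabel("frequency (animal-days)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def relaxed_rank_selection(
    records: pd.DataFrame,
    dist: DegreeDistribution,
    label: str,
    k: int,
    sex: pd.Series | dict | None = None,
    restrict_sex: str | None = None,
    n_required: int = 3,
    score_days: str = "last",
) -> pd.DataFrame:
    """Fill a target cohort of ``k`` animals for one label, relaxing the rule.

    Strictly classified animals (per :func:`classify`) are taken first.  If
    fewer than ``k`` qualify, remaining slots are filled with unclassified
    animals ranked by how closely their mean degree (over the selection
    days) approaches the threshold from the correct side of the population
    mean — e.g. for ``label='high'``: mean degree above ``dist.mean``,
    highest first.  Ties are broken by lexicographically lower ``tag_id``.
    Relaxed picks get ``relaxed=True`` and score = mean degree over their
    ``n_required`` most recent observed days.

    If the population holds fewer than ``k`` eligible animals, all of them
    are returned and the result is flagged via the ``short`` attribute
    ``DataFrame.attrs['short']``.
    """
    if label not in {"high", "low"}:
        raise ValueError("label must be 'high' or 'low'")
    if k < 0:
        raise ValueError("k must be non-negative")
    sex_map = dict(sex) if sex is not None else {}
    assigned = classify(records, dist, n_required=n_required, score_days=score_days, sex=sex)
    if restrict_sex is not None:
        eligible_tags = {t for t, s in sex_map.items() if s == restrict_sex}
        assigned = assigned[assigned["tag_id"].isin(eligible_tags)]

    strict = assigned[assigned["label"] == label].copy()
    strict["relaxed"] = False
    strict = strict.sort_values("tag_id", ignore_index=True)
    if len(strict) >= k:
        out = strict.iloc[:k].reset_index(drop=True)
        out.attrs["short"] = False
        return out

    pool = assigned[assigned["label"] == "unclassified"].copy()
    means = records.groupby("tag_id")["degree"].mean()
    pool["mean_degree"] = pool["tag_id"].map(means)
    if label == "high":
        pool = pool[pool["mean_degree"] > dist.mean]
        pool = pool.sort_values(["mean_degree", "tag_id"],
                                ascending=[False, True], kind="mergesort")
    else:
        pool = pool[pool["mean_degree"] < dist.mean]
        pool = pool.sort_values(["mean_degree", "tag_id"],
                                ascending=[True, True], kind="mergesort")
    fill = pool.iloc[: k - len(strict)].copy()
    if not fill.empty:
        fill["label"] = label
        fill["relaxed"] = True
        fill["reason"] = "relaxed_rank_fill"
        scores = []
        quals = []
        for tag in fill["tag_id"]:
            grp = records[records["tag_id"] == tag].drop_duplicates(subset="day")
            days = sorted(grp["day"])[-n_required:]
            sel = grp[grp["day"].isin(days)]
            scores.append(float(sel["degree"].mean()))
            quals.append(";".join(str(d) for d in days))
        fill["score"] = scores
        fill["qualifying_days"] = quals
        fill = fill.drop(columns=["mean_degree"])
    out = pd.concat([strict, fill], ignore_index=True)
    out.attrs["short"] = len(out) < k
    return out
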