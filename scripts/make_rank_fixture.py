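"""One-time generator for the frozen rank-ANOVA fixture (synthetic).

Writes ``tests/data/rank_anova_fixture.csv`` — a synthetic 2x2 cohort with
the study-like cell sizes 7/7/8/7 and planted sex and phenotype effects —
and ``tests/data/rank_anova_fixture_expected.json`` with reference results
computed by a route independent of the production optimizer: the Jaeckel /
Wilcoxon dispersion is minimized EXACTLY via its equivalent linear program

    min_beta sum_{i<j} |(y_i - y_j) - (x_i - x_j) beta|
    (D = sqrt(12) / (2 (n+1)) of that optimum)

solved with HiGHS, for the full model and each drop-one-term reduction;
the drop-in-dispersion F uses the package's tau estimator on the LP
residuals.  Committed outputs are frozen; re-running this script must
reproduce them byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import f as fdist

from greganet.rankstats import tau_estimate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "tests" / "data"


def lp_rank_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact Wilcoxon-dispersion minimizer via the pairwise-difference LP."""
    n, p = X.shape
    i, j = np.triu_indices(n, 1)
    dX = X[i] - X[j]
    dy = y[i] - y[j]
    m = dy.size
    A = np.zeros((2 * m, p + m))
    A[:m, :p] = dX
    A[m:, :p] = -dX
    A[:m, p:] = -np.eye(m)
    A[m:, p:] = -np.eye(m)
    b = np.concatenate([dy, -dy])
    c = np.concatenate([np.zeros(p), np.ones(m)])
    res = linprog(c, A_ub=A, b_ub=b,
                  bounds=[(None, None)] * p + [(0, None)] * m, method="highs")
    assert res.status == 0, res.message
    return res.x[:p], float(np.sqrt(12.0) / (2.0 * (n + 1)) * res.fun)


def main() -> None:
    rng = np.random.default_rng(20)
    sex = np.array(["F"] * 14 + ["M"] * 15)
    phen = np.array(["high"] * 7 + ["low"] * 7 + ["high"] * 7 + ["low"] * 8)
    male = (sex == "M").astype(float)
    high = (phen == "high").astype(float)
    y = 6.0 + 5.0 * male + 5.0 * high + rng.normal(0.0, 2.5, size=29)
    y = np.round(y, 2)
    df = pd.DataFrame({
        "tag_id": [f"T{i + 1:03d}" for i in range(29)],
        "sex": sex, "phenotype": phen, "value": y,
    })
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "rank_anova_fixture.csv", index=False)

    ca = np.where(sex == np.sort(np.unique(sex))[0], 1.0, -1.0)
    cb = np.where(phen == np.sort(np.unique(phen))[0], 1.0, -1.0)
    X = np.column_stack([ca, cb, ca * cb])
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta_full, d_full = lp_rank_fit(Xc, yc)
    tau = tau_estimate(y - X @ beta_full, p=3)

    n = 29
    rows = []
    for idx, term in enumerate(["sex", "phenotype", "sex:phenotype"]):
        _, d_red = lp_rank_fit(np.delete(Xc, idx, axis=1), yc)
        rd = max(d_red - d_full, 0.0)
        fstat = rd / (tau / 2.0)
        rows.append({
            "term": term, "F": fstat, "df1": 1, "df2": n - 3 - 1,
            "p": float(fdist.sf(fstat, 1, n - 3 - 1)),
        })
    expected = {
        "note": "synthetic reference output, computed once by the LP route in "
                "scripts/make_rank_fixture.py",
        "dispersion_full": d_full,
        "tau": tau,
        "coef_full": beta_full.tolist(),
        "table": rows,
    }
    (OUT / "rank_anova_fixture_expected.json").write_text(
        json.dumps(expected, indent=1, sort_keys=True)
    )
    print(json.dumps(expected, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
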