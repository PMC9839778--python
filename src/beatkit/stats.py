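"""Statistics used across the experiments: two-sided Fisher exact test,
two-sided Student's t-test, group summaries, and 2^-ddCt qPCR fold changes.

The Fisher p-value follows the probability-mass summation convention (the
one standard statistical software uses): with margins fixed, sum the
hypergeometric probabilities of all tables at most as probable as the
observed one. The computation is done in exact integer arithmetic, so ties
are exact rather than tolerance-based.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool = False


@dataclass
class TTestResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False


@dataclass
class DdctResult:
    """Per-replicate and summarized 2^-ddCt fold changes."""

    per_replicate: pd.DataFrame  # condition, gene, biological_replicate, fold
    summary: pd.DataFrame  # condition, gene, mean_fold, sd_fold, n


def fisher_exact_two_sided(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    p is the sum of hypergeometric probabilities (margins fixed) of every
    table with probability at most that of the observed one, computed with
    exact integer binomial coefficients. The odds ratio is ad/bc (infinite
    when bc = 0 with ad > 0). A zero margin makes the table degenerate and
    returns p = 1 by convention.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValidationError("need a 2x2 table of non-negative counts")
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    if n < 1:
        raise ValidationError("table total must be >= 1")

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)

    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return FisherResult(p_value=1.0, odds_ratio=odds, degenerate=True)

    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    observed = weights[a]
    total = comb(n, c1)
    mass = sum(w for w in weights.values() if w <= observed)
    return FisherResult(p_value=mass / total, odds_ratio=odds)


def student_t_two_sided(x, y, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test (equal-variance Student by default).

    ``welch=True`` uses the Welch statistic with Satterthwaite degrees of
    freedom. With zero variance in both samples: equal means give t = 0,
    p = 1; unequal means are flagged degenerate (p = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny_ = len(x), len(y)
    if nx < 2 or ny_ < 2:
        raise ValidationError("each sample needs n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if mx == my:
            return TTestResult(t=0.0, df=float(nx + ny_ - 2), p_value=1.0)
        return TTestResult(
            t=np.inf if mx > my else -np.inf,
            df=float(nx + ny_ - 2),
            p_value=0.0,
            degenerate=True,
        )
    if welch:
        se2x, se2y = vx / nx, vy / ny_
        t = (mx - my) / sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny_ - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny_ - 1) * vy) / (nx + ny_ - 2)
        t = (mx - my) / sqrt(sp2 * (1.0 / nx + 1.0 / ny_))
        df = float(nx + ny_ - 2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_value=float(min(p, 1.0)))


REQUIRED_QPCR_COLUMNS = (
    "condition",
    "biological_replicate",
    "gene",
    "ct",
)


def ddct_fold_change(
    table: pd.DataFrame,
    reference_gene: str = "eef1b2",
    control_condition: str = "control",
) -> DdctResult:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged per (condition, biological replicate,
    gene); dCt = Ct_gene - Ct_reference per biological replicate;
    ddCt = dCt - mean(dCt of the control condition); fold = 2^-ddCt.
    Folds are reported per replicate for every condition (controls are
    centered on their own mean, so their mean fold is ~1), with mean and
    n-1 standard deviation per (condition, gene).
    """
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table is missing columns {missing}")
    if np.any(table["ct"].to_numpy(dtype=float) <= 0):
        raise ValidationError("Ct values must be positive")

    # technical replicates averaged first
    ct = (
        table.groupby(["condition", "biological_replicate", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "biological_replicate"])["ct"]
    genes = ct[ct["gene"] != reference_gene]
    if genes.empty:
        raise ValidationError("no target genes besides the reference")

    rows = []
    for (cond, rep, gene), sub in genes.groupby(
        ["condition", "biological_replicate", "gene"], sort=True
    ):
        key = (cond, rep)
        if key not in ref.index:
            raise ValidationError(
                f"reference gene {reference_gene!r} missing for sample "
                f"condition={cond}, biological_replicate={rep}"
            )
        rows.append(
            {
                "condition": cond,
                "biological_replicate": rep,
                "gene": gene,
                "dct": float(sub["ct"].iloc[0]) - float(ref.loc[key]),
            }
        )
    dct = pd.DataFrame(rows)
    conditions = set(dct["condition"])
    if control_condition not in conditions:
        raise ValidationError(f"control condition {control_condition!r} absent")

    out = []
    for gene, sub in dct.groupby("gene", sort=True):
        control_mean = sub.loc[sub["condition"] == control_condition, "dct"].mean()
        for _, row in sub.iterrows():
            ddct = row["dct"] - control_mean
            out.append(
                {
                    "condition": row["condition"],
                    "gene": gene,
                    "biological_replicate": row["biological_replicate"],
                    "fold": 2.0 ** (-ddct),
                }
            )
    per_rep = pd.DataFrame(out)
    summary = (
        per_rep.groupby(["condition", "gene"], sort=True)["fold"]
        .agg(mean_fold="mean", sd_fold=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return DdctResult(per_replicate=per_rep, summary=summary)


def _tukey_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2
    return float(np.median(v[:half])), med, float(np.median(v[n - half:]))


def group_summary(values) -> dict:
    """Mean, s.d. (n-1), SEM and inclusive-median quartiles of a sample.

    A single value yields NaN s.d./SEM with ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("group_summary requires at least one value")
    q1, med, q3 = _tukey_quartiles(v)
    if v.size == 1:
        sd = sem = float("nan")
        degenerate = True
    else:
        sd = float(v.std(ddof=1))
        sem = sd / sqrt(v.size)
        degenerate = False
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": sd,
        "sem": sem,
        "min": float(v.min()),
        "q1": q1,
        "median": med,
        "q3": q3,
        "max": float(v.max()),
        "degenerate": degenerate,
    }
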