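"""Developmental-competence statistics: stage-transition rates and t-tests.

Pooled transition rates are 100 * numerator / denominator, rounded half-up
to one decimal (the convention used for printed percentages); conditional
transitions (e.g. 2-cell -> 4-cell) use the previous stage's count as the
denominator. Replicate rates are compared between conditions by unpaired
two-tailed Student's t-tests with pooled variance.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .types import OutcomeTable


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def transition_rates(table: OutcomeTable, decimals: int = 1) -> pd.DataFrame:
    """Pooled percentage per (condition, transition), rounded half-up."""
    t = table.table
    zero = t[t["denominator"] == 0]
    if len(zero):
        bad = zero.iloc[0]
        raise ValueError(
            f"zero denominator for {bad['condition']}:{bad['transition']}"
        )
    out = t.copy()
    out["rate_percent"] = [
        round_half_up(100.0 * n / d, decimals)
        for n, d in zip(t["numerator"], t["denominator"])
    ]
    return out


def ttest_rates(a, b) -> tuple[float, int, float]:
    """Unpaired two-tailed Student's t-test with pooled variance.

    Returns (t, df, two-sided p). Degenerate zero-variance inputs: equal
    means give p = 1; unequal means give p = 0 (flagged by t = +/- inf).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t_stat = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return float(t_stat), df, p


def pairwise_ttests(replicate_rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All condition pairs per transition from a long table
    (condition, transition, rate)."""
    rows = []
    for transition, sub in replicate_rates.groupby("transition"):
        conds = sorted(sub["condition"].unique())
        for i, c1 in enumerate(conds):
            for c2 in conds[i + 1 :]:
                a = sub.loc[sub["condition"] == c1, "rate"].to_numpy()
                b = sub.loc[sub["condition"] == c2, "rate"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                t_stat, df, p = ttest_rates(a, b)
                rows.append(
                    {
                        "transition": transition,
                        "condition_a": c1,
                        "condition_b": c2,
                        "t": t_stat,
                        "df": df,
                        "p": p,
                        "significant": p < alpha,
                    }
                )
    return pd.DataFrame(rows)
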