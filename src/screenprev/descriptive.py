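"""Administrative-prevalence arithmetic and crude descriptive summaries.

Administrative (registry) prevalence is a simple proportion — registered
cases over the target population — reported per 1,000 with a Wald 95%
confidence interval (an exact Clopper–Pearson interval is available and is
substituted with a flag when the Wald interval degenerates at zero counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class AdminCount:
    """Registered case count over a population denominator for one period."""

    period: str
    cases: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not (0 <= self.cases <= self.total):
            raise ValueError("cases must lie in [0, total]")


@dataclass(frozen=True)
class ProportionEstimate:
    """Point estimate and 95% CI per 1,000 (full precision; round for display)."""

    point: float
    lower: float
    upper: float
    method: str = "wald"
    flagged: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper):
            raise ValueError("requires 0 <= lower <= point <= upper")

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (round(self.point, ndigits), round(self.lower, ndigits),
                round(self.upper, ndigits))

    def __str__(self) -> str:
        p, lo, hi = self.rounded()
        return f"{p:.1f} per 1,000 (95% CI {lo:.1f}-{hi:.1f})"


def admin_prevalence(count: AdminCount, method: str = "wald") -> ProportionEstimate:
    """Registry prevalence per 1,000 with a binomial 95% CI.

    ``method`` is ``"wald"`` (normal approximation, the registry-table
    convention) or ``"exact"`` (Clopper–Pearson).  A zero or saturated count
    makes the Wald interval degenerate; the exact interval is then returned
    with a flag.
    """
    p = count.cases / count.total
    flagged = ""
    if method == "wald" and count.cases in (0, count.total):
        method, flagged = "exact", "wald interval degenerate at boundary count"
    sm_method = {"wald": "normal", "exact": "beta"}[method]
    lo, hi = proportion_confint(count.cases, count.total, alpha=0.05, method=sm_method)
    lo, hi = max(0.0, float(lo)), min(1.0, float(hi))
    return ProportionEstimate(point=1000.0 * p, lower=1000.0 * lo, upper=1000.0 * hi,
                              method=method, flagged=flagged)


def admin_table(counts: list[AdminCount]) -> pd.DataFrame:
    """Registry-style table: one column per period, one-decimal display values."""
    cols = {}
    for c in counts:
        est = admin_prevalence(c)
        p, lo, hi = est.rounded()
        cols[c.period] = {"cases": c.cases, "total": c.total,
                          "prevalence_per_1000": p, "ci_95": f"{lo:.1f}-{hi:.1f}"}
    return pd.DataFrame(cols)


def read_admin_counts(path) -> list[AdminCount]:
    """Read a period,cases,total CSV (mid-dot decimal marks tolerated)."""
    df = pd.read_csv(path, dtype=str)
    need = {"period", "cases", "total"}
    if not need.issubset(df.columns):
        raise ValueError(f"admin CSV must have columns {sorted(need)}")

    def _int(s: str) -> int:
        return int(str(s).replace("·", ".").replace(" ", "").replace(",", ""))

    return [AdminCount(row["period"], _int(row["cases"]), _int(row["total"]))
            for _, row in df.iterrows()]


def sex_ratio(male_cases: int, female_cases: int) -> float:
    """Male:female case ratio; undefined (NaN) when there are no female cases."""
    if male_cases < 0 or female_cases < 0:
        raise ValueError("case counts must be non-negative")
    if female_cases == 0:
        return float("nan")
    return male_cases / female_cases


def percent_change(old_value: float, new_value: float) -> float:
    """Relative change 100 * (new - old) / old."""
    if old_value <= 0:
        raise ValueError("old_value must be positive")
    return 100.0 * (new_value - old_value) / old_value


def coverage_fraction(sampled: int, target: int) -> float:
    """Sampling coverage 100 * sampled / target, in percent."""
    if target <= 0:
        raise ValueError("target must be positive")
    if not (0 <= sampled <= target):
        raise ValueError("sampled must lie in [0, target]")
    return 100.0 * sampled / target
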