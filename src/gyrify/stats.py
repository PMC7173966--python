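"""Group summaries and two-sample Student's t-tests from summary statistics.

Group results are carried as (mean, dispersion, n) where the dispersion is
either a standard deviation (SD) or a standard error of the mean
(SEM = SD/√n); the two are interconvertible.  The default test is the
two-tailed pooled-variance (equal-variance) Student's t:

    sp² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2)
    t   = (m₁ − m₂) / (sp · √(1/n₁ + 1/n₂)),   df = n₁+n₂−2

which is the variant that reproduces the printed p-values of the
independent-group comparisons this package ships as reference data.
Welch and one-tailed variants are available but non-default.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± dispersion with sample size for one group of animals."""

    mean: float
    dispersion: float
    dispersion_kind: str  # "SD" | "SEM"
    n: int

    def __post_init__(self):
        if self.dispersion_kind not in ("SD", "SEM"):
            raise ValueError("dispersion_kind must be 'SD' or 'SEM'")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n < 2:
            raise ValueError("a group needs n >= 2")

    @property
    def sd(self) -> float:
        return self.dispersion if self.dispersion_kind == "SD" else self.dispersion * math.sqrt(self.n)

    @property
    def sem(self) -> float:
        return self.dispersion / math.sqrt(self.n) if self.dispersion_kind == "SD" else self.dispersion


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    tails: int = 2
    variance_model: str = "pooled"


def summarize(values, dispersion_kind: str = "SD") -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and n for a list of raw values."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to summarise")
    sd = float(np.std(values, ddof=1))
    disp = sd if dispersion_kind == "SD" else sd / math.sqrt(values.size)
    return GroupSummary(
        mean=float(values.mean()), dispersion=disp, dispersion_kind=dispersion_kind, n=values.size
    )


def students_t_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    equal_var: bool = True,
    tails: int = 2,
) -> TTestResult:
    """Two-sample Student's t-test from group summaries.

    SEM dispersions are converted to SD internally.  Degenerate inputs:
    identical means with zero pooled variance give t = 0, p = 1; unequal
    means with zero variance are an error (infinite t).
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    s1, s2 = g1.sd, g2.sd
    n1, n2 = g1.n, g2.n
    delta = g1.mean - g2.mean
    if equal_var:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        df: float = n1 + n2 - 2
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        model = "pooled"
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if (v1 + v2) > 0 else float("nan")
        model = "welch"
    if se == 0:
        if delta == 0:
            return TTestResult(t=0.0, df=df, p=1.0, tails=tails, variance_model=model)
        raise ZeroDivisionError("zero variance with unequal means: t is infinite")
    t = delta / se
    p = tails * float(sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=min(p, 1.0), tails=tails, variance_model=model)


def decimals_of(printed: str) -> int:
    """Number of decimal places in a printed value like '0.0003'."""
    printed = printed.strip()
    if "e" in printed or "E" in printed:
        # scientific notation: use the exponent's implied decimals
        mantissa, exp = printed.lower().split("e")
        frac = len(mantissa.split(".")[1]) if "." in mantissa else 0
        return frac - int(exp)
    return len(printed.split(".")[1]) if "." in printed else 0


def rounds_to_printed(p: float, printed: str) -> bool:
    """Does a computed p-value round to the printed value at its precision?"""
    return round(p, decimals_of(printed)) == float(printed)


def build_report(comparisons, equal_var: bool = True, tails: int = 2) -> pd.DataFrame:
    """Tidy comparison table: one row per (comparison, metric).

    ``comparisons`` is an iterable of mappings/tuples with keys
    (label, metric, group1_name, g1, group2_name, g2) where g1/g2 are
    :class:`GroupSummary`; extra keys (analysis parameters) are carried
    through for provenance.
    """
    rows = []
    for comp in comparisons:
        if not isinstance(comp, dict):
            label, metric, name1, g1, name2, g2 = comp
            comp = {
                "label": label,
                "metric": metric,
                "group1": name1,
                "g1": g1,
                "group2": name2,
                "g2": g2,
            }
        g1, g2 = comp["g1"], comp["g2"]
        res = students_t_from_summary(g1, g2, equal_var=equal_var, tails=tails)
        row = {
            "label": comp.get("label"),
            "metric": comp.get("metric"),
            "group1": comp.get("group1"),
            "mean1": g1.mean,
            "dispersion1": g1.dispersion,
            "kind1": g1.dispersion_kind,
            "n1": g1.n,
            "group2": comp.get("group2"),
            "mean2": g2.mean,
            "dispersion2": g2.dispersion,
            "kind2": g2.dispersion_kind,
            "n2": g2.n,
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "p_2sig": float(f"{res.p:.2g}"),
            "tails": res.tails,
            "variance_model": res.variance_model,
        }
        for key, val in comp.items():
            if key not in row and key not in ("g1", "g2"):
                row[key] = val
        rows.append(row)
    columns = [
        "label", "metric", "group1", "mean1", "dispersion1", "kind1", "n1",
        "group2", "mean2", "dispersion2", "kind2", "n2",
        "t", "df", "p", "p_2sig", "tails", "variance_model",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)
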