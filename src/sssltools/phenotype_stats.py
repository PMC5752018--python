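"""Per-line phenotype summaries and Dunnett's many-to-one comparison.

Each substitution line is compared against the single recurrent parent
(control).  With *k* treatment lines in a one-way equal-variance layout, the
*k* pairwise t statistics share the control sample, so they follow a joint
multivariate t distribution with correlation ``rho_ij = lambda_i * lambda_j``
where ``lambda_i = sqrt(n_i / (n_i + n0))``.  Dunnett's adjustment computes,
for each observed ``|t_i|``, the familywise probability that the maximum of
the *k* absolute statistics exceeds it under the joint null.  In the
factored representation

    T_i = (lambda_i * Z0 + sqrt(1 - lambda_i**2) * E_i) / sqrt(W / df)

(``Z0, E_i`` iid standard normal, ``W ~ chi2(df)``) the statistics are
independent given ``(Z0, W)``, so

    P(max_i |T_i| < c) = E_{Z0,W}[ prod_i Phi(u_i) - Phi(l_i) ]

with ``u_i, l_i`` the conditional bounds.  We evaluate the outer expectation
by seeded Monte Carlo and the inner product exactly (a Rao-Blackwellized
estimator), which is unbiased, handles unbalanced group sizes, and has far
lower variance than sampling the maximum directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "LineSummary",
    "DunnettResult",
    "summarize_lines",
    "dunnett_test",
    "call_qtl_presence",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("line_id", "year", "plant_id", "days_to_heading")


class PhenotypeTable:
    """Per-plant days-to-heading records keyed by line and year.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``line_id, year, plant_id, days_to_heading``.  Rows with missing
    trait values are dropped with a warning (never imputed).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        n_missing = df["days_to_heading"].isna().sum()
        if n_missing:
            logger.warning("dropping %d plants with missing days_to_heading", n_missing)
            df = df.dropna(subset=["days_to_heading"])
        if df.empty:
            raise ValueError("phenotype table has no usable records")
        if (df["days_to_heading"] <= 0).any():
            bad = df.loc[df["days_to_heading"] <= 0]
            raise ValueError(f"non-positive days_to_heading for lines {sorted(bad['line_id'].unique())}")
        df["line_id"] = df["line_id"].astype(str)
        df["year"] = df["year"].astype(str)
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "PhenotypeTable":
        return cls(pd.DataFrame(records, columns=list(REQUIRED_COLUMNS)))

    def years(self) -> list[str]:
        return sorted(self.df["year"].unique())

    def lines(self, year: Optional[str] = None) -> list[str]:
        df = self.df if year is None else self.df[self.df["year"] == year]
        return sorted(df["line_id"].unique())

    def values(self, line_id: str, year: Optional[str] = None) -> np.ndarray:
        df = self.df[self.df["line_id"] == str(line_id)]
        if year is not None:
            df = df[df["year"] == str(year)]
        return df["days_to_heading"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class LineSummary:
    line_id: str
    year: str
    n: int
    mean: float
    sem: float

    def __str__(self) -> str:  # Table-style "mean±sem"
        return f"{self.mean:.2f}±{self.sem:.2f}"


@dataclass(frozen=True)
class DunnettResult:
    line_id: str
    year: str
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float


def summarize_lines(pheno: PhenotypeTable) -> list[LineSummary]:
    """Mean and standard error (sample SD / sqrt(n)) per line and year."""
    out = []
    for (line, year), grp in pheno.df.groupby(["line_id", "year"], sort=True):
        x = grp["days_to_heading"].to_numpy(dtype=float)
        n = len(x)
        if n < 2:
            raise ValueError(f"line {line!r} year {year!r} has {n} plant(s); need >=2 for SEM")
        out.append(
            LineSummary(
                line_id=line,
                year=year,
                n=n,
                mean=float(np.mean(x)),
                sem=float(np.std(x, ddof=1) / math.sqrt(n)),
            )
        )
    return out


def _dunnett_pvalues(
    thresholds: np.ndarray, lambdas: np.ndarray, df: int, mc_draws: int, seed: int
) -> np.ndarray:
    """Adjusted p-values P(max_j |T_j| >= c) for each threshold c.

    Monte Carlo over the shared control variate Z0 and the pooled-variance
    scale, with the conditional probability product over treatments computed
    exactly (see module docstring).
    """
    from scipy.special import ndtr

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(mc_draws)
    s = np.sqrt(rng.chisquare(df, mc_draws) / df)
    w = np.sqrt(1.0 - lambdas**2)
    out = np.empty(thresholds.size)
    for i, c in enumerate(np.abs(thresholds)):
        if c == 0.0:
            out[i] = 1.0
            continue
        # (draws, k): conditional P(|T_j| < c | Z0, W) per treatment
        upper = (c * s[:, None] - lambdas * z0[:, None]) / w
        lower = (-c * s[:, None] - lambdas * z0[:, None]) / w
        out[i] = 1.0 - float(np.mean(np.prod(ndtr(upper) - ndtr(lower), axis=1)))
    return np.clip(out, 0.0, 1.0)


def dunnett_test(
    pheno: PhenotypeTable,
    control_line: str,
    alpha: float = 0.01,
    mc_draws: int = 100_000,
    seed: int = 0,
    year: Optional[str] = None,
) -> list[DunnettResult]:
    """Two-sided Dunnett many-to-one test of every line against the control.

    Years are analysed as separate families (the trials are independent
    plantings); pass ``year`` to restrict to one.  P-values are adjusted for
    the family of k comparisons via the Monte Carlo max-|t| tail described in
    the module docstring; with k = 1 they reduce to the pooled two-sample t
    test up to Monte Carlo error.

    Raises if the control is absent, if there is no treatment line, or if the
    pooled variance is zero while some group mean differs from the control's
    (constant data with equal means yields p = 1 for every line).
    """
    years = [year] if year is not None else pheno.years()
    results: list[DunnettResult] = []
    for yr in years:
        lines = pheno.lines(yr)
        if control_line not in lines:
            raise ValueError(f"control line {control_line!r} absent in year {yr!r}")
        treatments = [l for l in lines if l != control_line]
        if not treatments:
            raise ValueError(f"no treatment lines in year {yr!r}")
        x0 = pheno.values(control_line, yr)
        groups = [pheno.values(l, yr) for l in treatments]
        for l, g in zip([control_line] + treatments, [x0] + groups):
            if len(g) < 2:
                raise ValueError(f"line {l!r} year {yr!r} has <2 plants")

        n0 = len(x0)
        ns = np.array([len(g) for g in groups])
        all_groups = [x0] + groups
        n_total = sum(len(g) for g in all_groups)
        df = n_total - len(all_groups)
        ss = sum(float(np.sum((g - np.mean(g)) ** 2)) for g in all_groups)
        s2 = ss / df

        means = np.array([np.mean(g) for g in groups])
        mean0 = float(np.mean(x0))
        if s2 == 0.0:
            if np.allclose(means, mean0):
                tstats = np.zeros(len(groups))
            else:
                raise ValueError("zero pooled variance with unequal group means")
        else:
            tstats = (means - mean0) / np.sqrt(s2 * (1.0 / ns + 1.0 / n0))

        lambdas = np.sqrt(ns / (ns + n0))
        pvals = _dunnett_pvalues(tstats, lambdas, df, mc_draws, seed)
        for line_id, t, p in zip(treatments, tstats, pvals):
            p = float(p)
            results.append(
                DunnettResult(
                    line_id=line_id,
                    year=yr,
                    t_statistic=float(t),
                    p_value=p,
                    significant=p <= alpha,
                    alpha=alpha,
                )
            )
    return results


def call_qtl_presence(
    results: Sequence[DunnettResult], alpha: float = 0.01
) -> dict[str, bool]:
    """Presence call per line: True iff the adjusted p-value is <= alpha.

    The threshold is inclusive (p exactly equal to alpha is a call).
    """
    return {r.line_id: r.p_value <= alpha for r in results}
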