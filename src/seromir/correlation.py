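"""Normality-gated correlation of marker ΔCt against clinical scores.

The analysis runs a planned family of correlation tests between the marker's
ΔCt and neuropsychiatric scores, both in a general scope (all patients and
controls) and in class-specific scopes (one patient class plus controls).
Each test is Pearson when both variables pass normality checks within the
scope and Spearman otherwise.  Two-sided p-values are corrected three ways
across the planned family of m tests (default m = 16, giving the Bonferroni
per-test threshold α/m = 0.05/16 ≈ 0.003): a Bonferroni verdict, Holm
step-down adjusted p, and Benjamini–Hochberg adjusted p.  Not-testable (NT)
records — zero-variance variables or too few pairs — still consume a family
slot.  Follow-up ordinary least-squares regression is offered for
correlations passing all three significance gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import normality_check
from .io import ADOS_COLUMNS, CohortTable
from .multitest import bh_adjust, bonferroni_threshold, holm_adjust


@dataclass(frozen=True)
class Scope:
    """A correlation scope: which cohort groups, and which score variables."""

    label: str
    groups: tuple[str, ...]
    variables: tuple[str, ...]


def default_scopes() -> tuple[Scope, ...]:
    """The planned 16-test family: one general and three class-specific scopes."""
    return (
        Scope("all patients and NCs", ("ASD", "TS", "TS+ASD", "NC"),
              ("IQ", "YGTSS", *ADOS_COLUMNS)),
        Scope("ASD patients and NCs", ("ASD", "NC"), ADOS_COLUMNS),
        Scope("TS patients and NCs", ("TS", "NC"), ("YGTSS",)),
        Scope("TS+ASD patients and NCs", ("TS+ASD", "NC"), ("YGTSS", *ADOS_COLUMNS)),
    )


@dataclass
class CorrelationRecord:
    """One ΔCt-vs-score correlation with all three corrections."""

    scope: str
    variable: str
    method: str  # "Pearson", "Spearman", or "NT" (not testable)
    n: int
    r: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p: float = math.nan
    bonferroni_significant: bool | None = None
    p_holm: float = math.nan
    p_bh: float = math.nan


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-transform CI; for Spearman this is the usual approximation."""
    if n < 4 or abs(r) >= 1.0:
        return (math.nan, math.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlate(
    marker: pd.Series,
    cohort: CohortTable,
    scopes: Sequence[Scope] | None = None,
    *,
    family_size: int = 16,
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Run the planned correlation family and apply all three corrections.

    ``marker`` maps sample id → ΔCt.  For each scope × variable, the method is
    gated on normality of BOTH variables within the scope (Shapiro–Wilk plus
    the K2 omnibus where group size allows): Pearson when both pass, Spearman
    otherwise.  ``family_size`` fixes the correction divisor m regardless of
    how many records turn out testable.
    """
    scopes = tuple(default_scopes() if scopes is None else scopes)
    n_planned = sum(len(s.variables) for s in scopes)
    if family_size < n_planned:
        raise ValueError(
            f"family_size {family_size} smaller than the {n_planned} planned tests"
        )

    records: list[CorrelationRecord] = []
    for scope in scopes:
        ids = [s for s in cohort.samples_in(scope.groups) if s in marker.index]
        for var in scope.variables:
            y_all = cohort.scores(var).reindex(ids)
            x_all = marker.reindex(ids)
            mask = x_all.notna() & y_all.notna()
            x = x_all[mask].to_numpy(dtype=float)
            y = y_all[mask].to_numpy(dtype=float)
            n = int(mask.sum())
            if n < 3 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                records.append(CorrelationRecord(scope.label, var, "NT", n))
                continue
            gate = (
                normality_check({"x": x}, alpha).normal
                and normality_check({"y": y}, alpha).normal
            )
            if gate:
                res = stats.pearsonr(x, y)
                method = "Pearson"
            else:
                res = stats.spearmanr(x, y)
                method = "Spearman"
            r, p = float(res.statistic), float(res.pvalue)
            ci = _fisher_ci(r, n, alpha)
            records.append(
                CorrelationRecord(scope.label, var, method, n, r, ci[0], ci[1], p)
            )

    testable = [rec for rec in records if rec.method != "NT"]
    if testable:
        p_raw = np.array([rec.p for rec in testable])
        thresh = bonferroni_threshold(alpha, family_size)
        p_holm = holm_adjust(p_raw, m=family_size)
        p_bh = bh_adjust(p_raw, m=family_size)
        for rec, ph, pb in zip(testable, p_holm, p_bh):
            rec.bonferroni_significant = bool(rec.p <= thresh)
            rec.p_holm = float(ph)
            rec.p_bh = float(pb)
    return records


def records_to_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """Tabular view of a correlation family, one row per planned test."""
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "variable": r.variable,
                "method": r.method,
                "n": r.n,
                "r": r.r,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "bonferroni_significant": r.bonferroni_significant,
                "p_holm": r.p_holm,
                "p_bh": r.p_bh,
            }
            for r in records
        ]
    )


def significant_records(
    records: Sequence[CorrelationRecord],
    *,
    alpha: float = 0.05,
    family_size: int = 16,
    holm_alpha: float = 0.05,
    bh_alpha: float = 0.01,
) -> list[CorrelationRecord]:
    """Records passing all three gates: Bonferroni α/m, Holm ≤ 0.05, BH ≤ 0.01.

    These are the correlations eligible for follow-up linear regression.
    """
    return [
        r
        for r in records
        if r.method != "NT"
        and r.bonferroni_significant
        and r.p_holm <= holm_alpha
        and r.p_bh <= bh_alpha
    ]


@dataclass
class LinearFit:
    """Ordinary least-squares line y = a·x + b with a two-sided slope test."""

    slope: float
    intercept: float
    p_value: float
    r_value: float
    stderr: float
    n: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"y = {self.slope:.3f}x {'+' if self.intercept >= 0 else '−'} "
            f"{abs(self.intercept):.3f}  (two-sided p = {self.p_value:.3g}, n = {self.n})"
        )


def fit_line(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit of score on ΔCt; errors on constant x or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least three complete (x, y) pairs")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant: slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )
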