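"""Differential expression on ΔCt matrices.

Two arms:

* a two-class unpaired SAM-style permutation test (discovery arm): a
  moderated relative-difference statistic d with fudge factor s0, and
  permutation-calibrated q-values with a configurable FDR cutoff;
* ordinary one-way ANOVA across the four cohort groups with Tukey's multiple
  comparisons (validation arm), preceded by D'Agostino–Pearson and
  Shapiro–Wilk normality checks.

SAM details (the method is named after its moderated statistic): for miRNA i,

    d_i = (mean₂ − mean₁) / (s_i + s0)

with s_i the pooled standard error and s0 a small positive offset damping the
statistic for low-variance features.  s0 is chosen from the percentile grid of
the s_i values to minimise the coefficient of variation of the median absolute
deviation of d across s-quantile windows (for very small feature counts the
grid is unstable and the median of s is used instead; s0 may always be
overridden).  The permutation FDR at threshold t is

    FDR(t) = mean_b #{j : |d*_{j,b}| ≥ t}  /  #{j : |d_j| ≥ t}

— the average count of features exceeding t in the label-permuted data over
the count in the observed data — and q_i is the minimum FDR over all observed
thresholds t ≤ |d_i| (the loosest-to-tightest monotonisation that makes q a
proper q-value), clipped to [0, 1].
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, GROUPS
from .normalize import DeltaCtMatrix, ExpressionComparison, fold_change

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SAM two-class unpaired test
# ---------------------------------------------------------------------------


@dataclass
class SamResult:
    """Per-feature SAM statistics and permutation q-values.

    ``table`` has columns ``d`` (relative difference), ``s`` (pooled SE),
    ``q`` (permutation FDR q-value), indexed by miRNA and sorted by |d|
    descending.  ``called`` is the set at ``q ≤ fdr_cutoff``.
    """

    table: pd.DataFrame
    s0: float
    n_perm: int
    exhaustive: bool
    fdr_cutoff: float
    dropped: tuple[str, ...]

    @property
    def called(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["q"] <= self.fdr_cutoff])


def _pooled_stats(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise (mean2 − mean1, pooled SE) with NaN-aware counts."""
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows under permutation
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
    ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
    ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / df)
    return m2 - m1, s


def choose_s0(d_num: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimising the CV of MAD(d) across s-quantile windows.

    Candidates are the 0th–100th percentiles of s in steps of 5.  With fewer
    than 20 features the window statistics are too noisy and the median of s
    is returned instead.
    """
    n = s.size
    if n < 20:
        return float(np.median(s))
    alphas = np.percentile(s, np.arange(0, 101, 5))
    n_windows = min(100, max(2, n // 10))
    edges = np.quantile(s, np.linspace(0.0, 1.0, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best, best_cv = float(np.median(s)), np.inf
    for s0 in alphas:
        d = d_num / (s + s0)
        mads = np.array(
            [stats.median_abs_deviation(d[window == w], scale="normal")
             for w in range(n_windows) if np.any(window == w)]
        )
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std(ddof=0) / mean
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def _permutation_assignments(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], bool]:
    """Index sets taking the role of group 1, exhaustive when feasible."""
    total = math.comb(n, n1)
    if total <= n_perm:
        combos = [np.array(c, dtype=int) for c in itertools.combinations(range(n), n1)]
        return combos, True
    picks = []
    for _ in range(n_perm):
        picks.append(rng.permutation(n)[:n1].copy())
    return picks, False


def sam_two_class(
    dct: DeltaCtMatrix | pd.DataFrame,
    g1: Sequence[str],
    g2: Sequence[str],
    *,
    fdr_cutoff: float = 0.15,
    n_perm: int = 100,
    seed: int | None = None,
    s0: float | None = None,
) -> SamResult:
    """Two-class unpaired SAM permutation test on a ΔCt matrix.

    ``g1``/``g2`` are sample-id lists (each ≥ 2).  At least ``n_perm`` label
    permutations are used unless fewer distinct assignments exist, in which
    case all are enumerated.  Features with no observation in either group are
    dropped with a logged note.
    """
    values = dct.values if isinstance(dct, DeltaCtMatrix) else dct
    g1, g2 = list(g1), list(g2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")
    if set(g1) & set(g2):
        raise ValueError("groups overlap")
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")

    x = values[g1 + g2].to_numpy(dtype=float)
    n1 = len(g1)
    ok = (np.sum(~np.isnan(x[:, :n1]), axis=1) >= 1) & (
        np.sum(~np.isnan(x[:, n1:]), axis=1) >= 1
    )
    dropped = tuple(values.index[~ok])
    if dropped:
        logger.info("SAM: dropping %d miRNA(s) entirely missing in a group", len(dropped))
    x = x[ok]
    index = values.index[ok]
    if x.shape[0] == 0:
        raise ValueError("no testable miRNAs")

    d_num, s = _pooled_stats(x[:, :n1], x[:, n1:])
    s0_val = choose_s0(d_num, s) if s0 is None else float(s0)
    d = d_num / (s + s0_val)
    abs_d = np.abs(d)

    rng = np.random.default_rng(seed)
    assignments, exhaustive = _permutation_assignments(x.shape[1], n1, n_perm, rng)

    # counts of permuted |d*| exceeding each observed threshold
    thresholds = np.sort(abs_d)  # ascending
    exceed = np.empty((len(assignments), thresholds.size))
    all_idx = np.arange(x.shape[1])
    for b, idx1 in enumerate(assignments):
        mask = np.zeros(x.shape[1], dtype=bool)
        mask[idx1] = True
        dn, sp = _pooled_stats(x[:, mask], x[:, ~mask])
        # a row may lose all observations of one pseudo-group under permutation;
        # its d* is undefined and counts as non-exceeding
        d_star = np.nan_to_num(np.abs(dn / (sp + s0_val)), nan=0.0)
        # #{j : |d*_j| >= t} for each ascending threshold t
        exceed[b] = d_star.size - np.searchsorted(np.sort(d_star), thresholds, side="left")
    mean_exceed = np.mean(exceed, axis=0)
    r_obs = abs_d.size - np.searchsorted(thresholds, thresholds, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.minimum(mean_exceed / r_obs, 1.0)
    # q_i = min FDR over thresholds t ≤ |d_i|: running min left-to-right over
    # ascending thresholds, then map each feature to its own threshold.
    q_cum = np.minimum.accumulate(fdr_at)
    pos = np.searchsorted(thresholds, abs_d, side="right") - 1
    q = q_cum[pos]

    table = pd.DataFrame({"d": d, "s": s, "q": q}, index=index)
    table = table.iloc[np.argsort(-np.abs(table["d"]), kind="stable")]
    return SamResult(
        table=table,
        s0=s0_val,
        n_perm=len(assignments),
        exhaustive=exhaustive,
        fdr_cutoff=fdr_cutoff,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Normality checks
# ---------------------------------------------------------------------------


@dataclass
class NormalityReport:
    """Per-group D'Agostino–Pearson K2 and Shapiro–Wilk results.

    ``per_group`` maps group name → dict with keys ``k2``, ``k2_p``, ``sw``,
    ``sw_p`` (NaN when a statistic is undefined) and ``note``.  The combined
    ``verdict`` is "non-normal" as soon as either test rejects in any group
    (or a group is degenerate), otherwise "normal".
    """

    per_group: dict[str, dict]
    alpha: float
    verdict: str

    @property
    def normal(self) -> bool:
        return self.verdict == "normal"


def normality_check(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> NormalityReport:
    """Run both normality tests per group and combine conservatively.

    The K2 omnibus statistic needs n ≥ 8 and is omitted (with a note) for
    smaller groups; Shapiro–Wilk needs n ≥ 3.  A constant vector leaves
    Shapiro–Wilk undefined and forces a non-normal verdict by convention.
    """
    per_group: dict[str, dict] = {}
    reject = False
    for name, raw in groups.items():
        x = np.asarray(raw, dtype=float)
        x = x[~np.isnan(x)]
        entry: dict = {"n": int(x.size), "k2": np.nan, "k2_p": np.nan,
                       "sw": np.nan, "sw_p": np.nan, "note": ""}
        if x.size < 3:
            entry["note"] = "too few observations for any normality test"
            reject = True
        elif np.ptp(x) == 0.0:
            entry["note"] = "constant vector: Shapiro-Wilk undefined; non-normal by convention"
            reject = True
        else:
            sw = stats.shapiro(x)
            entry["sw"], entry["sw_p"] = float(sw.statistic), float(sw.pvalue)
            if entry["sw_p"] < alpha:
                reject = True
            if x.size >= 8:
                k2 = stats.normaltest(x)
                entry["k2"], entry["k2_p"] = float(k2.statistic), float(k2.pvalue)
                if entry["k2_p"] < alpha:
                    reject = True
            else:
                entry["note"] = "n < 8: K2 omitted, verdict from Shapiro-Wilk alone"
        per_group[name] = entry
    return NormalityReport(
        per_group=per_group, alpha=alpha, verdict="non-normal" if reject else "normal"
    )


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey's multiple comparisons
# ---------------------------------------------------------------------------


@dataclass
class AnovaTukeyResult:
    """Ordinary one-way ANOVA with Tukey-adjusted pairwise comparisons."""

    mirna: str
    f_statistic: float
    p_value: float
    pairs: pd.DataFrame  # columns: group1, group2, diff, p_adj, fold_change
    group_summary: pd.DataFrame  # n, mean, sd per group
    alpha: float

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["p_adj"] <= self.alpha]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA for {self.mirna}: F = {self.f_statistic:.4g}, "
            f"p = {self.p_value:.4g}",
            self.group_summary.to_string(),
            self.pairs.to_string(index=False),
        ]
        return "\n\n".join(lines)


def anova_tukey(
    dct: DeltaCtMatrix | pd.DataFrame,
    cohort: CohortTable,
    mirna: str,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA of a miRNA's ΔCt across cohort groups, then Tukey HSD.

    Adjusted pairwise p-values come from the studentized-range distribution
    (deterministic); pairwise fold changes are 2^−ΔΔCt.
    """
    values = dct.values if isinstance(dct, DeltaCtMatrix) else dct
    row = values.loc[mirna]
    arrays: dict[str, np.ndarray] = {}
    for g in GROUPS:
        ids = [s for s in cohort.samples_in([g]) if s in row.index]
        x = row[ids].dropna().to_numpy(dtype=float)
        if x.size >= 2:
            arrays[g] = x
    if len(arrays) < 2:
        raise ValueError("need at least two groups with ≥ 2 samples each")
    if all(np.ptp(x) == 0.0 for x in arrays.values()):
        raise ValueError("zero within-group variance everywhere: F undefined")

    names = list(arrays)
    f_stat, p = stats.f_oneway(*arrays.values())
    hsd = stats.tukey_hsd(*arrays.values())

    group_ids = {g: [s for s in cohort.samples_in([g]) if s in row.index] for g in names}
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        gi, gj = names[i], names[j]
        fc = fold_change(values, group_ids[gi], group_ids[gj], mirna)
        rows.append(
            {
                "group1": gi,
                "group2": gj,
                "diff": float(np.mean(arrays[gi]) - np.mean(arrays[gj])),
                "p_adj": float(hsd.pvalue[i, j]),
                "fold_change": fc.fold_change,
            }
        )
    pairs = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "n": {g: x.size for g, x in arrays.items()},
            "mean": {g: float(np.mean(x)) for g, x in arrays.items()},
            "sd": {g: float(np.std(x, ddof=1)) for g, x in arrays.items()},
        }
    )
    return AnovaTukeyResult(
        mirna=mirna,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairs=pairs,
        group_summary=summary,
        alpha=alpha,
    )
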