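"""Endogenous-control selection and ΔCt normalization for Ct matrices.

The normalization strategy mirrors the customary practice for serum qPCR
arrays where no validated reference gene exists: per comparison, build a
per-sample reference profile (median and mean Ct over all fully detected
miRNAs, reflecting the loaded cDNA mass), rank miRNAs by how positively their
Ct profile correlates with that reference, and normalize to the mean Ct of the
top few stable, abundant miRNAs.  Any miRNA with even one flagged well among
the comparison's samples is excluded from the reference and from ranking.

Conventions: ΔCt = Ct(target) − reference(sample); lower ΔCt means higher
relative expression.  Fold change between groups is 2^−ΔΔCt with
ΔΔCt = mean ΔCt(group1) − mean ΔCt(group2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReferenceProfile:
    """Per-sample median/mean Ct over rows with no flagged well."""

    median: pd.Series
    mean: pd.Series
    excluded: frozenset[str]
    samples: tuple[str, ...]


@dataclass
class ControlRanking:
    """Correlation ranking of candidate endogenous controls.

    ``table`` has one row per rankable miRNA with columns ``r_median``,
    ``r_mean``, ``r`` (the ranking key), ``mean_ct`` (abundance; lower =
    more abundant), and ``rank`` (1 = best).  ``selected`` is the final
    control set: among the ``m`` most stable miRNAs, the ``k`` most abundant.
    """

    table: pd.DataFrame
    selected: tuple[str, ...]
    k: int
    m: int
    by: str


@dataclass
class DeltaCtMatrix:
    """Reference-normalized expression: ΔCt = Ct − mean Ct of the controls.

    ``values`` is miRNA × sample with NaN where the target well was flagged;
    ``reference`` is the per-sample control mean that was subtracted, so
    ``values + reference`` reconstructs the (masked) Ct matrix.
    """

    values: pd.DataFrame
    controls: tuple[str, ...]
    reference: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def mirnas(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def marker(self, mirna: str) -> pd.Series:
        return self.values.loc[mirna]


@dataclass
class ExpressionComparison:
    """Two-group ΔCt comparison: ΔΔCt and fold change 2^−ΔΔCt."""

    mirna: str
    mean_g1: float
    mean_g2: float
    n_g1: int
    n_g2: int

    @property
    def delta_delta_ct(self) -> float:
        return self.mean_g1 - self.mean_g2

    @property
    def fold_change(self) -> float:
        return float(2.0 ** (-self.delta_delta_ct))


def excluded_mirnas(ct: CtMatrix, samples: Sequence[str] | None = None) -> frozenset[str]:
    """MiRNAs with ≥1 flagged well among ``samples`` (whole matrix if None)."""
    flag = ct.flag if samples is None else ct.flag[list(samples)]
    return frozenset(flag.index[flag.any(axis=1)])


def build_reference_profile(
    ct: CtMatrix, samples: Sequence[str] | None = None
) -> ReferenceProfile:
    """Per-sample median and mean Ct over fully detected miRNAs.

    A miRNA is dropped from both statistics in *every* sample as soon as one
    of its wells among the chosen samples is flagged.
    """
    samples = list(ct.samples if samples is None else samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples for a reference profile")
    sub = ct.subset(samples)
    excluded = excluded_mirnas(sub)
    kept = sub.ct.drop(index=excluded)
    if kept.shape[0] == 0:
        raise ValueError("no unflagged complete rows: every miRNA has a flagged well")
    if kept.shape[0] < 2:
        raise ValueError("fewer than two unflagged complete rows")
    return ReferenceProfile(
        median=kept.median(axis=0),
        mean=kept.mean(axis=0),
        excluded=excluded,
        samples=tuple(samples),
    )


def rank_endogenous_controls(
    ct: CtMatrix,
    profile: ReferenceProfile,
    k: int = 3,
    *,
    m: int = 10,
    by: Literal["average", "median", "mean"] = "average",
) -> ControlRanking:
    """Rank candidate endogenous controls by correlation to the reference.

    Each fully detected miRNA's Ct vector is Pearson-correlated with the
    per-sample median profile and with the mean profile; the ranking key is,
    by default, the average of the two correlations (``by`` selects either
    single profile instead).  Ranking is descending in r, with ties broken by
    lower mean Ct then miRNA id.  Selection is two-stage: among the top ``m``
    most stable miRNAs, the ``k`` most abundant (lowest mean Ct) become the
    controls — stability first, then the abundance preference.

    Zero-variance rows carry no profile information (r undefined) and are
    excluded from ranking with a logged note.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if m < k:
        raise ValueError("m must be ≥ k")
    samples = list(profile.samples)
    sub = ct.subset(samples)
    candidates = sub.ct.drop(index=excluded_mirnas(sub))
    med = profile.median.to_numpy(dtype=float)
    mean_prof = profile.mean.to_numpy(dtype=float)
    if np.std(med) == 0.0 or np.std(mean_prof) == 0.0:
        raise ValueError("reference profile is constant across samples; r undefined")

    rows = []
    for mirna, row in candidates.iterrows():
        x = row.to_numpy(dtype=float)
        if np.std(x) == 0.0:
            logger.info("excluding zero-variance miRNA %r from control ranking", mirna)
            continue
        r_med = float(np.corrcoef(x, med)[0, 1])
        r_mean = float(np.corrcoef(x, mean_prof)[0, 1])
        rows.append((mirna, r_med, r_mean, float(np.mean(x))))
    if not rows:
        raise ValueError("no rankable miRNAs (all excluded or zero-variance)")

    table = pd.DataFrame(rows, columns=["miRNA", "r_median", "r_mean", "mean_ct"])
    if by == "average":
        table["r"] = (table["r_median"] + table["r_mean"]) / 2.0
    elif by == "median":
        table["r"] = table["r_median"]
    elif by == "mean":
        table["r"] = table["r_mean"]
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    # descending r; ties: lower mean Ct (more abundant), then lexicographic id
    table = table.sort_values(
        ["r", "mean_ct", "miRNA"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.set_index("miRNA")

    top_m = table.head(min(m, len(table)))
    chosen = top_m.sort_values(["mean_ct", "r", "rank"], ascending=[True, False, True])
    selected = tuple(chosen.index[: min(k, len(chosen))])
    return ControlRanking(table=table, selected=selected, k=k, m=m, by=by)


def compute_delta_ct(
    ct: CtMatrix,
    controls: Sequence[str],
    *,
    samples: Sequence[str] | None = None,
    on_flagged_control: Literal["error", "drop_sample"] = "error",
) -> DeltaCtMatrix:
    """ΔCt = Ct(target, sample) − mean Ct of the controls in that sample.

    Cells whose target well is flagged are missing (NaN).  A flagged control
    well leaves that sample's reference undefined: this is an error unless
    ``on_flagged_control="drop_sample"``, which removes the sample.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("controls must be non-empty")
    samples = list(ct.samples if samples is None else samples)
    sub = ct.subset(samples)
    missing = [c for c in controls if c not in sub.mirnas]
    if missing:
        raise KeyError(f"controls not in matrix: {missing}")

    ctrl_flags = sub.flag.loc[controls]
    bad_samples = list(ctrl_flags.columns[ctrl_flags.any(axis=0)])
    if bad_samples:
        if on_flagged_control == "error":
            raise ValueError(
                f"flagged control well(s) leave the reference undefined in samples {bad_samples}"
            )
        logger.warning("dropping sample(s) with flagged control wells: %s", bad_samples)
        keep = [s for s in samples if s not in bad_samples]
        if not keep:
            raise ValueError("all samples dropped: every sample has a flagged control well")
        sub = sub.subset(keep)

    reference = sub.ct.loc[controls].mean(axis=0)
    values = sub.masked.sub(reference, axis=1)
    return DeltaCtMatrix(
        values=values,
        controls=tuple(controls),
        reference=reference,
        provenance={"samples": list(sub.samples), "panel": sub.panel},
    )


def fold_change(
    dct: DeltaCtMatrix | pd.DataFrame,
    g1: Sequence[str],
    g2: Sequence[str],
    mirna: str,
) -> ExpressionComparison:
    """Fold change 2^−ΔΔCt of ``mirna`` between sample groups g1 and g2."""
    values = dct.values if isinstance(dct, DeltaCtMatrix) else dct
    row = values.loc[mirna]
    x1 = row[list(g1)].dropna()
    x2 = row[list(g2)].dropna()
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError(f"empty group after removing missing ΔCt for {mirna!r}")
    return ExpressionComparison(
        mirna=mirna,
        mean_g1=float(x1.mean()),
        mean_g2=float(x2.mean()),
        n_g1=len(x1),
        n_g2=len(x2),
    )


def select_and_normalize(
    ct: CtMatrix,
    samples: Sequence[str] | None = None,
    k: int = 3,
    *,
    m: int = 10,
    on_flagged_control: Literal["error", "drop_sample"] = "drop_sample",
) -> tuple[DeltaCtMatrix, ControlRanking, ReferenceProfile]:
    """One-call pipeline: reference profile → control ranking → ΔCt.

    This is the per-comparison workflow: the exclusion set, profile, and
    ranking are all recomputed on exactly the samples of the comparison.
    """
    profile = build_reference_profile(ct, samples)
    ranking = rank_endogenous_controls(ct, profile, k=k, m=m)
    dct = compute_delta_ct(
        ct, ranking.selected, samples=profile.samples, on_flagged_control=on_flagged_control
    )
    dct.provenance.update(
        {
            "selected_controls": list(ranking.selected),
            "excluded": sorted(profile.excluded),
        }
    )
    return dct, ranking, profile
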