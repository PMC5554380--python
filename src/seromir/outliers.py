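"""Mean ± 2·SD outlier screening of marker expression and clinical items.

Within a candidate group, each screened variable defines the interval
[mean − 2·SD, mean + 2·SD] on the pre-exclusion data (single pass, sample SD
with the n−1 denominator).  A sample is out of range on a variable when its
value lies strictly outside the interval.  Exclusion combines the expression
variable with the item variables under one of two rules:

``"and"`` (default)
    excluded iff out of range on the expression variable AND on ≥ 1 item;
``"or"``
    excluded iff out of range on the expression variable OR on ≥ 1 item.

An audit log records which variables triggered each exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class OutlierScreen:
    """Intervals, per-sample out-of-range flags, exclusions, and audit log."""

    intervals: dict[str, tuple[float, float]]
    flags: pd.DataFrame  # samples × variables, boolean
    excluded: tuple[str, ...]
    audit: tuple[dict, ...]
    rule: str
    expression_var: str


def screen_outliers(
    table: pd.DataFrame,
    expression_var: str,
    item_vars: Sequence[str],
    *,
    rule: Literal["and", "or"] = "and",
    n_sd: float = 2.0,
) -> OutlierScreen:
    """Screen samples against mean ± ``n_sd``·SD ranges.

    ``table`` is indexed by sample id; ``expression_var`` and every name in
    ``item_vars`` must be numeric columns.  Each screened variable needs ≥ 3
    non-missing values (all-missing is an error naming the variable); a
    zero-SD variable screens nobody.  Missing values are never out of range.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    variables = [expression_var, *item_vars]
    if len(set(variables)) != len(variables):
        raise ValueError("screened variables must be distinct")

    intervals: dict[str, tuple[float, float]] = {}
    flags = pd.DataFrame(False, index=table.index, columns=variables)
    for var in variables:
        x = pd.to_numeric(table[var], errors="raise")
        n_obs = int(x.notna().sum())
        if n_obs == 0:
            raise ValueError(f"all values missing for screened variable {var!r}")
        if n_obs < 3:
            raise ValueError(f"screened variable {var!r} needs ≥ 3 non-missing values")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        lo, hi = mean - n_sd * sd, mean + n_sd * sd
        intervals[var] = (lo, hi)
        if sd > 0.0:
            flags[var] = ((x < lo) | (x > hi)).fillna(False)

    expr_out = flags[expression_var]
    item_out = flags[list(item_vars)].any(axis=1) if item_vars else pd.Series(
        False, index=table.index
    )
    if rule == "and":
        excluded_mask = expr_out & item_out
    else:
        excluded_mask = expr_out | item_out

    audit = []
    for sample in table.index[excluded_mask]:
        audit.append(
            {
                "sample": sample,
                "triggered_by": [v for v in variables if flags.at[sample, v]],
            }
        )
    return OutlierScreen(
        intervals=intervals,
        flags=flags,
        excluded=tuple(table.index[excluded_mask]),
        audit=tuple(audit),
        rule=rule,
        expression_var=expression_var,
    )
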