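"""Text I/O for Ct matrices, ΔCt tables, cohort metadata, edge lists, and gene sets.

All formats are plain TSV/CSV/GMT dialects.  A TaqMan array export is modelled
as a miRNA × sample matrix of cycle-threshold (Ct) values in which failed or
"Undetermined" amplifications appear as sentinel tokens; these become a boolean
flag mask that every downstream stage treats as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid cohort group labels: autism spectrum disorder, Tourette syndrome,
#: comorbid TS+ASD, and unaffected negative controls.
GROUPS: tuple[str, ...] = ("ASD", "TS", "TS+ASD", "NC")

#: Default sentinel tokens marking a flagged (failed/undetermined) well.
DEFAULT_SENTINELS: frozenset[str] = frozenset({"Undetermined", "NA", ""})

#: Clinical score columns of a cohort table.  ADOS items A–D are the
#: Communication, Social interaction, Imagination, and Repetitive and
#: restricted behaviors item scores.
SCORE_COLUMNS: tuple[str, ...] = ("IQ", "YGTSS", "ADOS_A", "ADOS_B", "ADOS_C", "ADOS_D")

ADOS_COLUMNS: tuple[str, ...] = ("ADOS_A", "ADOS_B", "ADOS_C", "ADOS_D")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Ct matrices
# ---------------------------------------------------------------------------


@dataclass
class CtMatrix:
    """Raw cycle-threshold values with a per-well flag mask.

    Parameters
    ----------
    ct
        miRNA × sample matrix of Ct values (PCR cycles, typically 10–40).
        Cells under a flag may hold any float (NaN when read from a sentinel);
        consumers must go through :attr:`masked`.
    flag
        Boolean mask of identical shape; ``True`` marks a flagged well
        (failed/undetermined amplification) whose Ct is not interpretable.
    panel
        Optional array panel label (e.g. ``"A"``/``"B"``).
    """

    ct: pd.DataFrame
    flag: pd.DataFrame
    panel: str | None = None

    def __post_init__(self) -> None:
        if not self.ct.index.equals(self.flag.index) or not self.ct.columns.equals(
            self.flag.columns
        ):
            raise ValueError("ct and flag must share identical row/column labels")
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate miRNA identifiers: {dups}")
        if self.ct.columns.has_duplicates:
            dups = self.ct.columns[self.ct.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        self.ct = self.ct.astype(float)
        self.flag = self.flag.astype(bool)

    @property
    def mirnas(self) -> pd.Index:
        return self.ct.index

    @property
    def samples(self) -> pd.Index:
        return self.ct.columns

    @property
    def masked(self) -> pd.DataFrame:
        """Ct values with every flagged well replaced by NaN."""
        return self.ct.where(~self.flag)

    @property
    def n_flagged(self) -> int:
        return int(self.flag.to_numpy().sum())

    def subset(self, samples: Sequence[str]) -> "CtMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.ct.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return CtMatrix(self.ct[samples].copy(), self.flag[samples].copy(), self.panel)


def read_ct_matrix(
    path: str | Path,
    *,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
    delimiter: str | None = None,
    panel: str | None = None,
) -> CtMatrix:
    """Read a miRNA × sample Ct matrix with sentinel-encoded flagged wells.

    The file must carry a header row of sample ids (first column = miRNA id)
    and one row per miRNA.  Cells are numeric, or one of ``sentinels`` to mark
    a flagged well.  A non-numeric, non-sentinel cell is a hard error naming
    its coordinates, as are duplicate row or column ids.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    sentinels = set(sentinels)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate miRNA identifiers in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers in {path}: {dups}")

    ct = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    flag = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        for row in raw.index:
            cell = raw.at[row, col].strip()
            if cell in sentinels:
                flag.at[row, col] = True
            else:
                try:
                    ct.at[row, col] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"non-numeric, non-sentinel cell {cell!r} at "
                        f"(miRNA={row!r}, sample={col!r}) in {path}"
                    ) from exc
    return CtMatrix(ct, flag, panel=panel)


def write_ct_matrix(
    matrix: CtMatrix,
    path: str | Path,
    *,
    sentinel: str = "Undetermined",
    delimiter: str | None = None,
) -> None:
    """Write a Ct matrix, encoding flagged wells as ``sentinel``."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    out = matrix.ct.astype(object).copy()
    out = out.where(~matrix.flag, sentinel)
    out.to_csv(path, sep=sep, index_label="miRNA")


# ---------------------------------------------------------------------------
# ΔCt tables (plain numeric matrices; missing values allowed)
# ---------------------------------------------------------------------------


def read_delta_ct_table(path: str | Path, *, delimiter: str | None = None) -> pd.DataFrame:
    """Read a miRNA × sample ΔCt table; empty/NA cells become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate row or column identifiers in {path}")
    return df.astype(float)


def write_delta_ct_table(
    values: pd.DataFrame, path: str | Path, *, delimiter: str | None = None
) -> None:
    path = Path(path)
    values.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="miRNA")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-sample group label plus clinical scores.

    ``table`` is indexed by sample id and carries a ``group`` column plus the
    score columns in :data:`SCORE_COLUMNS` (missing scores are NaN; unaffected
    controls carry ADOS = 0 by convention).  Extra columns are preserved
    untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        if "group" not in self.table.columns:
            raise FormatError("cohort table needs a 'group' column")
        bad = sorted(set(self.table["group"]) - set(GROUPS))
        if bad:
            raise FormatError(f"unknown group labels: {bad} (expected one of {GROUPS})")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_sizes(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def samples_in(self, groups: Iterable[str]) -> list[str]:
        wanted = set(groups)
        bad = wanted - set(GROUPS)
        if bad:
            raise KeyError(f"unknown group labels: {sorted(bad)}")
        return list(self.table.index[self.groups.isin(wanted)])

    def scores(self, column: str) -> pd.Series:
        return self.table[column].astype(float)


def read_cohort(
    path: str | Path,
    *,
    delimiter: str | None = None,
    case_fold: bool = False,
) -> CohortTable:
    """Read a cohort TSV/CSV with columns sample, group, IQ, YGTSS, ADOS_A..D.

    Group labels are validated against the four-level vocabulary; with
    ``case_fold`` they are first upper-cased (``"asd"`` → ``"ASD"``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if "sample" not in df.columns:
        raise FormatError("cohort table needs a 'sample' column")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    if case_fold and "group" in df.columns:
        df["group"] = df["group"].astype(str).str.upper()
    for col in SCORE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path, *, delimiter: str | None = None) -> None:
    path = Path(path)
    cohort.table.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="sample")


# ---------------------------------------------------------------------------
# Gene sets and interaction networks
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, genes…) into term → gene-set."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description, ≥1 gene")
            term = fields[0]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = {g for g in fields[2:] if g}
            sets[term] = genes
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, term, *sorted(genes)]) + "\n")


def read_edge_list(path: str | Path, *, delimiter: str | None = None) -> nx.Graph:
    """Read a two-column TSV (or three-column SIF) edge list into an
    undirected, deduplicated graph.  Self-loops are dropped with a warning."""
    path = Path(path)
    graph = nx.Graph()
    dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: source relation target
                a, _, b = fields
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) columns")
            if a == b:
                dropped += 1
                continue
            graph.add_edge(a, b)
    if dropped:
        logger.warning("dropped %d self-loop(s) while reading %s", dropped, path)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in graph.edges():
            fh.write(f"{a}\t{b}\n")
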