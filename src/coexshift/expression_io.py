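"""Loading, probe collapsing and candidate-gene subsetting of expression data.

Input is a normalized (e.g. VSN or log-scale) probe- or gene-level matrix as
tab-delimited text, or a GEO series-matrix-style file whose numeric body sits
between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.  A
series-matrix-style file may additionally carry a platform annotation block
(``!platform_table_begin`` .. ``!platform_table_end``) from which a
probe-to-gene-symbol map is read.

Probes interrogating the same transcript are collapsed to one gene row by
per-sample arithmetic averaging.  Gene symbols are matched case-insensitively
and without alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_DISEASE = "disease"
GROUP_NORMAL = "normal"

#: separators that mark an ambiguous multi-symbol probe annotation
_AMBIGUOUS_SEPARATORS = ("///", ";", "|")

#: column names accepted as the gene-symbol column of a platform table
_SYMBOL_COLUMNS = ("GENE_SYMBOL", "Gene Symbol", "SYMBOL", "gene_symbol", "symbol")


class ExpressionIOError(ValueError):
    """Raised for malformed expression, design or gene-list inputs."""


@dataclass
class ProbeMatrix:
    """Probe-level matrix straight off disk, before collapsing to genes.

    ``values`` has probe ids as the index and sample ids as columns;
    ``probe_to_gene`` is populated when the file supplied an annotation block,
    otherwise the user provides the map separately.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str] | None = None


@dataclass
class GeneList:
    """Ordered, unique candidate gene symbols."""

    symbols: list[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ExpressionIOError("gene list is empty")
        seen: set[str] = set()
        ordered: list[str] = []
        for s in self.symbols:
            key = s.strip().casefold()
            if not key:
                continue
            if key not in seen:
                seen.add(key)
                ordered.append(s.strip())
        self.symbols = ordered

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a two-group sample design.

    ``values``: genes as index, samples as columns, numeric, no missing
    entries.  ``groups``: maps every sample id to ``"disease"`` or
    ``"normal"``; both groups must be non-empty.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene ids after collapsing: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample ids: {dups}")
        self.groups = self.groups.astype(str).str.strip().str.lower()
        unknown = set(self.groups.unique()) - {GROUP_DISEASE, GROUP_NORMAL}
        if unknown:
            raise ExpressionIOError(
                f"group labels must be '{GROUP_DISEASE}' or '{GROUP_NORMAL}', got {sorted(unknown)}"
            )
        missing_design = [s for s in self.values.columns if s not in self.groups.index]
        if missing_design:
            raise ExpressionIOError(f"samples missing from design: {missing_design}")
        self.groups = self.groups.loc[self.values.columns]
        for grp in (GROUP_DISEASE, GROUP_NORMAL):
            if not (self.groups == grp).any():
                raise ExpressionIOError(f"group '{grp}' has no samples")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ExpressionIOError(f"missing values in rows: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_of(self, group: str) -> list[str]:
        return self.groups.index[self.groups == group].tolist()

    def group_values(self, group: str) -> np.ndarray:
        """Genes x samples array restricted to one group's columns."""
        return self.values.loc[:, self.samples_of(group)].to_numpy(dtype=float)


@dataclass
class SubsetResult:
    """Outcome of restricting a matrix to a candidate gene list."""

    matrix: ExpressionMatrix
    found: list[str]
    missing: list[str]

    @property
    def n_found(self) -> int:
        return len(self.found)

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def _check_header_unique(header_fields: list[str], path: Path) -> None:
    # pandas silently mangles duplicate column names, so inspect the raw header
    samples = [f.strip().strip('"') for f in header_fields[1:]]
    seen: set[str] = set()
    dups: set[str] = set()
    for s in samples:
        if s in seen:
            dups.add(s)
        seen.add(s)
    if dups:
        raise ExpressionIOError(f"{path}: duplicate sample ids {sorted(dups)}")


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    _check_header_unique(header.split("\t"), path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    return _coerce_numeric(df, path)


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ExpressionIOError(f"{path}: duplicate sample ids {dups}")
    out = df.apply(pd.to_numeric, errors="coerce")
    # blank cells stay NaN (missing-value policy applies later); cells that
    # held text are a parse error and must be reported with their location
    nonblank = df.fillna("").apply(lambda col: col.astype(str).str.strip() != "")
    bad = out.isna() & nonblank
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionIOError(
            f"{path}: non-numeric cell at row '{out.index[r]}', column '{out.columns[c]}': "
            f"{df.iat[r, c]!r}"
        )
    return out


def _read_series_matrix(path: Path) -> ProbeMatrix:
    """Parse the series-matrix dialect: matrix body between the begin/end
    markers, optional platform annotation block for the probe->gene map."""
    matrix_lines: list[str] = []
    platform_lines: list[str] = []
    in_matrix = in_platform = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            low = stripped.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                in_matrix = True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_matrix = False
                continue
            if low.startswith("!platform_table_begin"):
                in_platform = True
                continue
            if low.startswith("!platform_table_end"):
                in_platform = False
                continue
            if in_matrix and stripped:
                matrix_lines.append(stripped)
            elif in_platform and stripped:
                platform_lines.append(stripped)
    if not matrix_lines:
        raise ExpressionIOError(f"{path}: no !series_matrix_table_begin/end block found")

    from io import StringIO

    _check_header_unique(matrix_lines[0].split("\t"), path)
    df = pd.read_csv(StringIO("\n".join(matrix_lines)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip().str.strip('"')
    df.columns = [c.strip().strip('"') for c in df.columns]
    values = _coerce_numeric(df, path)

    probe_to_gene: dict[str, str] | None = None
    if platform_lines:
        ann = pd.read_csv(StringIO("\n".join(platform_lines)), sep="\t", dtype=str)
        ann.columns = [c.strip().strip('"') for c in ann.columns]
        sym_col = next((c for c in _SYMBOL_COLUMNS if c in ann.columns), None)
        if sym_col is None:
            raise ExpressionIOError(
                f"{path}: platform table lacks a gene-symbol column "
                f"(expected one of {_SYMBOL_COLUMNS})"
            )
        id_col = ann.columns[0]
        probe_to_gene = {
            str(row[id_col]).strip().strip('"'): str(row[sym_col]).strip().strip('"')
            for _, row in ann.iterrows()
            if pd.notna(row[sym_col]) and str(row[sym_col]).strip()
        }
    return ProbeMatrix(values=values, probe_to_gene=probe_to_gene)


def load_expression(path: str | Path, format: str = "tsv") -> ProbeMatrix:
    """Read a probe-level expression matrix from disk.

    Parameters
    ----------
    path:
        Tab-delimited matrix (first column row ids, header row sample ids) or
        a series-matrix-style file.
    format:
        ``"tsv"`` or ``"series_matrix"``.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"expression file not found: {path}")
    if format == "tsv":
        return ProbeMatrix(values=_read_tsv_matrix(path))
    if format == "series_matrix":
        return _read_series_matrix(path)
    raise ExpressionIOError(f"unknown expression format: {format!r}")


def load_design(path: str | Path) -> pd.Series:
    """Read a two-column TSV of sample id -> group label (disease/normal)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: design file needs two columns (sample, group)")
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in (GROUP_DISEASE, GROUP_NORMAL):  # tolerate a header row
        df = df.iloc[1:]
    samples = df.iloc[:, 0].astype(str).str.strip()
    if samples.duplicated().any():
        raise ExpressionIOError(f"{path}: duplicate sample ids in design")
    return pd.Series(df.iloc[:, 1].astype(str).str.strip().str.lower().to_numpy(),
                     index=samples.to_numpy())


def load_gene_list(path: str | Path) -> GeneList:
    """Read candidate gene symbols, one per line (``#`` comments allowed)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line.split("\t")[0])
    return GeneList(symbols)


def load_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping probe id -> gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionIOError(f"{path}: probe map needs two columns (probe, symbol)")
    return dict(zip(df.iloc[:, 0].astype(str).str.strip(),
                    df.iloc[:, 1].astype(str).str.strip()))


def _is_ambiguous(symbol: str) -> bool:
    return any(sep in symbol for sep in _AMBIGUOUS_SEPARATORS)


def collapse_probes(
    probe_matrix: ProbeMatrix | pd.DataFrame,
    probe_to_gene: Mapping[str, str] | None = None,
    groups: pd.Series | None = None,
    missing: str = "reject",
) -> ExpressionMatrix | pd.DataFrame:
    """Average all probes interrogating the same transcript into one gene row.

    Probes with no gene mapping, or with an ambiguous multi-symbol mapping,
    are dropped and counted in the log.  ``missing="reject"`` (default) raises
    on rows with missing entries; ``missing="impute"`` replaces each gap with
    that gene's within-group mean (requires ``groups``).

    Returns an :class:`ExpressionMatrix` when ``groups`` is given, otherwise
    the collapsed gene-by-sample :class:`pandas.DataFrame`.
    """
    if isinstance(probe_matrix, ProbeMatrix):
        values = probe_matrix.values
        if probe_to_gene is None:
            probe_to_gene = probe_matrix.probe_to_gene
    else:
        values = probe_matrix
    if probe_to_gene is None:
        raise ExpressionIOError("no probe-to-gene map supplied or embedded in the file")

    mapping = {str(p).strip(): str(g).strip() for p, g in probe_to_gene.items()}
    unmapped = [p for p in values.index if p not in mapping or not mapping[p]]
    ambiguous = [p for p in values.index if p in mapping and _is_ambiguous(mapping[p])]
    keep = [p for p in values.index if p in mapping and mapping[p] and not _is_ambiguous(mapping[p])]
    if unmapped:
        logger.info("collapse_probes: dropped %d probes with no gene mapping", len(unmapped))
    if ambiguous:
        logger.info("collapse_probes: dropped %d probes with ambiguous mapping", len(ambiguous))
    if not keep:
        raise ExpressionIOError("no probe maps to any gene symbol")

    kept = values.loc[keep]
    symbols = pd.Index([mapping[p] for p in keep], name=values.index.name)
    collapsed = kept.groupby(symbols.str.upper(), sort=False).mean()
    # present each gene under the first-seen spelling of its symbol
    first_spelling = {}
    for p in keep:
        key = mapping[p].upper()
        first_spelling.setdefault(key, mapping[p])
    collapsed.index = [first_spelling[g] for g in collapsed.index]

    if collapsed.isna().any().any():
        if missing == "impute":
            if groups is None:
                raise ExpressionIOError("missing='impute' requires a group design")
            g = groups.astype(str).str.strip().str.lower()
            for grp in (GROUP_DISEASE, GROUP_NORMAL):
                cols = [c for c in collapsed.columns if c in g.index and g[c] == grp]
                block = collapsed.loc[:, cols]
                collapsed.loc[:, cols] = block.T.fillna(block.mean(axis=1)).T
            if collapsed.isna().any().any():
                raise ExpressionIOError("imputation failed: a gene has no observed value in a group")
        elif missing == "drop":
            collapsed = collapsed.dropna(axis=0)
        else:
            bad = collapsed.index[collapsed.isna().any(axis=1)].tolist()
            raise ExpressionIOError(f"rows with missing values (policy 'reject'): {bad}")

    if groups is None:
        return collapsed
    return ExpressionMatrix(values=collapsed, groups=groups)


def subset_to_genes(matrix: ExpressionMatrix, genes: GeneList | Iterable[str]) -> SubsetResult:
    """Restrict the matrix to the candidate list, preserving list order.

    Matching is case-insensitive exact symbol comparison.  Raises on an empty
    intersection; found/missing counts are reported on the result.
    """
    if not isinstance(genes, GeneList):
        genes = GeneList(list(genes))
    by_key = {g.casefold(): g for g in matrix.gene_ids}
    found = [by_key[s.casefold()] for s in genes if s.casefold() in by_key]
    missing = [s for s in genes if s.casefold() not in by_key]
    if not found:
        raise ExpressionIOError("no candidate gene found in the expression matrix")
    logger.info("subset_to_genes: %d of %d candidate genes found (%d missing)",
                len(found), len(genes), len(missing))
    sub = ExpressionMatrix(values=matrix.values.loc[found].copy(), groups=matrix.groups.copy())
    return SubsetResult(matrix=sub, found=found, missing=missing)
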