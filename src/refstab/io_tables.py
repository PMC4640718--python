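"""Reading and writing gene×sample tables and result reports.

All inputs are delimited text: a matrix file with gene ids in the first
column and one column per sample, plus a sample-metadata file with columns
``sample_id`` and ``group`` (an optional ``time_point`` column is carried
along untouched). Output reports are TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "NA"


class TableFormatError(ValueError):
    """Raised for malformed input tables (duplicates, bad cells, missing metadata)."""


@dataclass
class CtMatrix:
    """Gene×sample threshold-cycle (Ct) values with sample groups.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Missing
        (undetermined) Ct values are stored as NaN.
    groups
        Series mapping sample id -> group label; must cover every sample.
    efficiencies
        Series mapping gene id -> amplification efficiency E (1 < E <= 2).
        Defaults to perfect doubling (E = 2) for every gene.
    """

    values: pd.DataFrame
    groups: pd.Series
    efficiencies: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        self.groups = pd.Series(self.groups, dtype=object)
        missing_meta = [s for s in self.values.columns if s not in self.groups.index]
        if missing_meta:
            raise TableFormatError(
                f"samples without group metadata: {missing_meta}"
            )
        self.groups = self.groups.loc[list(self.values.columns)]
        if len(self.groups) and self.groups.isna().any():
            raise TableFormatError("every sample needs a non-null group label")
        if self.efficiencies is None:
            self.efficiencies = pd.Series(2.0, index=self.values.index)
        else:
            self.efficiencies = pd.Series(self.efficiencies, dtype=float).reindex(
                self.values.index
            )
            if self.efficiencies.isna().any():
                bad = list(self.efficiencies.index[self.efficiencies.isna()])
                raise TableFormatError(f"genes without efficiency: {bad}")
        if (self.efficiencies <= 1.0).any():
            bad = list(self.efficiencies.index[self.efficiencies <= 1.0])
            raise TableFormatError(f"amplification efficiency must be > 1; bad: {bad}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy()).any():
                raise TableFormatError("Ct values must be finite or missing (NaN)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def drop_incomplete_samples(self) -> "CtMatrix":
        """Return a copy without any sample that has a missing Ct for any gene."""
        keep = self.values.columns[~self.values.isna().any(axis=0)]
        dropped = [s for s in self.values.columns if s not in set(keep)]
        if dropped:
            logger.info("dropping %d incomplete sample(s): %s", len(dropped), dropped)
        return CtMatrix(
            self.values[keep].copy(), self.groups.loc[keep].copy(), self.efficiencies.copy()
        )


@dataclass
class ExpressionMatrix:
    """Gene×sample linear-scale (non-negative) expression quantities."""

    values: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.groups is not None:
            self.groups = pd.Series(self.groups, dtype=object)
            missing = [s for s in self.values.columns if s not in self.groups.index]
            if missing:
                raise TableFormatError(f"samples without group metadata: {missing}")
            self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _check_unique(ids: Sequence, kind: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise TableFormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


def _read_raw_table(path: str | Path, delimiter: str) -> tuple[list[str], list[str], list[list[str]]]:
    """Read a delimited matrix as raw strings: (sample ids, gene ids, rows)."""
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise TableFormatError(f"{path}: no data rows")
    header = lines[0].split(delimiter)
    samples = [h.strip() for h in header[1:]]
    _check_unique(samples, "sample")
    genes: list[str] = []
    rows: list[list[str]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delimiter)]
        if len(cells) != len(samples) + 1:
            raise TableFormatError(
                f"{path}: row {cells[0]!r} has {len(cells) - 1} cells, expected {len(samples)}"
            )
        genes.append(cells[0])
        rows.append(cells[1:])
    _check_unique(genes, "gene")
    return samples, genes, rows


def read_sample_metadata(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read sample metadata with columns sample_id, group [, time_point]."""
    meta = pd.read_csv(path, sep=delimiter, dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise TableFormatError(f"{path}: metadata needs columns sample_id and group")
    _check_unique(list(meta["sample_id"]), "sample")
    return meta.set_index("sample_id")


def read_ct_table(
    path: str | Path,
    metadata_path: str | Path,
    *,
    delimiter: str = "\t",
    missing_token: str = DEFAULT_MISSING_TOKEN,
    efficiencies: Mapping[str, float] | None = None,
) -> CtMatrix:
    """Load a Ct matrix plus its sample metadata.

    Non-numeric cells are hard errors unless they equal ``missing_token``,
    in which case the Ct is flagged missing (NaN). The number of loaded
    cells plus flagged-missing cells always equals the input cell count.
    """
    samples, genes, rows = _read_raw_table(path, delimiter)
    data = np.empty((len(genes), len(samples)), dtype=float)
    n_missing = 0
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == missing_token:
                data[i, j] = math.nan
                n_missing += 1
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric Ct {cell!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r} (missing token is {missing_token!r})"
                ) from None
    meta = read_sample_metadata(metadata_path, delimiter)
    groups = meta["group"]
    values = pd.DataFrame(data, index=genes, columns=samples)
    eff = pd.Series(efficiencies, dtype=float) if efficiencies is not None else None
    ct = CtMatrix(values, groups, eff)
    if n_missing:
        logger.info("%s: %d Ct value(s) flagged missing", path, n_missing)
    return ct


def read_expression_matrix(
    path: str | Path,
    *,
    delimiter: str = "\t",
    metadata_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a linear-scale expression matrix; negative entries are hard errors."""
    samples, genes, rows = _read_raw_table(path, delimiter)
    data = np.empty((len(genes), len(samples)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric value {cell!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
    groups = None
    if metadata_path is not None:
        groups = read_sample_metadata(metadata_path, delimiter)["group"]
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples), groups)


def write_report(result, path: str | Path) -> None:
    """Write any result object as a TSV report.

    Dispatches on the result type: anything exposing ``to_frame()`` (the
    geNorm/NormFinder/ranking result classes), a DataFrame, or a list of
    dataclass records. Re-reading a written ranking reproduces its order.
    """
    if hasattr(result, "to_frame"):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result
    elif isinstance(result, (list, tuple)):
        frame = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in result])
    else:
        raise TypeError(f"cannot serialise {type(result).__name__} as a report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
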