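"""Expression-matrix data model, I/O and normalization.

Everything downstream of this module (differential expression, the consensus
screen, patient-side statistics) works on a log2-scale genes x samples matrix
plus a sample sheet binding each sample to a cohort and a sensitive/resistant
condition.  Inputs declared as linear counts are log2(x+1)-transformed at
load; missing values are rejected, not imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("sensitive", "resistant")


class ExpressionParseError(ValueError):
    """Structured parse/validation failure naming the offending row/column."""


@dataclass(frozen=True)
class CohortPair:
    """One sensitive/resistant cell-line pair (the screen's voting unit)."""

    cohort_id: str
    sensitive_samples: tuple[str, ...]
    resistant_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sensitive_samples or not self.resistant_samples:
            raise ValueError(
                f"cohort {self.cohort_id!r}: both arms must be non-empty"
            )
        if set(self.sensitive_samples) & set(self.resistant_samples):
            raise ValueError(
                f"cohort {self.cohort_id!r}: arms share samples"
            )


class SampleSheet:
    """Sample -> (cohort, condition) binding.

    Wraps a DataFrame with columns ``sample_id``, ``cohort_id``,
    ``condition`` (condition in {sensitive, resistant}).
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["sample_id", "cohort_id", "condition"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ExpressionParseError(
                f"sample sheet missing column(s) {missing}"
            )
        frame = frame[required].astype(str).copy()
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise ExpressionParseError(
                f"duplicate sample_id(s) in sheet: {sorted(set(dup))}"
            )
        bad = frame.loc[~frame["condition"].isin(CONDITIONS), "condition"]
        if len(bad):
            raise ExpressionParseError(
                f"condition must be one of {CONDITIONS}; got {sorted(set(bad))}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def cohort_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["cohort_id"]))

    def cohort_pairs(self) -> list[CohortPair]:
        """One CohortPair per cohort; errors if an arm is empty."""
        pairs = []
        for cid, grp in self.frame.groupby("cohort_id", sort=False):
            sens = tuple(grp.loc[grp["condition"] == "sensitive", "sample_id"])
            res = tuple(grp.loc[grp["condition"] == "resistant", "sample_id"])
            pairs.append(CohortPair(str(cid), sens, res))
        return pairs

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples expression values.

    ``data`` is indexed by gene_id with sample_id columns.  Values must be
    finite; gene ids must be unique unless the matrix is explicitly passed
    through :func:`collapse_duplicates`.
    """

    data: pd.DataFrame
    allow_duplicate_genes: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        vals = self.data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()]
            raise ExpressionParseError(
                f"duplicate sample id(s): {sorted(set(dups))}"
            )
        if not self.allow_duplicate_genes and self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()]
            raise ExpressionParseError(
                f"duplicate gene id(s) without collapse: {sorted(set(dups))[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ExpressionParseError(f"unknown sample id(s): {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)])


def read_expression(
    matrix_path,
    sheet_path=None,
    *,
    collapse: bool = False,
    linear_counts: bool = False,
):
    """Load an expression TSV (and optionally its sample sheet).

    The TSV's first column is ``gene_id``; remaining columns are sample ids.
    ``linear_counts=True`` applies log2(x+1) at load (for count-scale inputs
    such as HTSeq counts); GEO-style array matrices are assumed log2 already.

    Returns ``ExpressionMatrix`` or ``(ExpressionMatrix, SampleSheet)`` when
    ``sheet_path`` is given.  Every sheet sample must be a matrix column.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ExpressionParseError(
            f"{matrix_path}: expected gene_id column plus >=1 sample column"
        )
    raw = raw.set_index(raw.columns[0])
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise ExpressionParseError(
            f"non-numeric cell at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionParseError(
            f"missing value at gene {numeric.index[r]!r}, "
            f"sample {numeric.columns[c]!r}"
        )
    if linear_counts:
        if (numeric.to_numpy() < 0).any():
            raise ExpressionParseError("negative value in linear-count matrix")
        numeric = np.log2(numeric + 1.0)
    matrix = ExpressionMatrix(numeric, allow_duplicate_genes=True)
    if collapse:
        matrix = collapse_duplicates(matrix)
    elif matrix.data.index.duplicated().any():
        dups = matrix.data.index[matrix.data.index.duplicated()]
        raise ExpressionParseError(
            f"duplicate gene id(s) without collapse flag: {sorted(set(dups))[:5]}"
        )
    else:
        matrix = ExpressionMatrix(matrix.data)

    if sheet_path is None:
        return matrix
    sheet = SampleSheet(pd.read_csv(sheet_path, sep="\t", dtype=str))
    missing = [s for s in sheet.sample_ids if s not in matrix.data.columns]
    if missing:
        raise ExpressionParseError(
            f"sheet sample(s) absent from matrix: {missing}"
        )
    return matrix, sheet


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Serialize to TSV with 6 significant digits."""
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def collapse_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse repeated gene ids, keeping the duplicate with maximal
    variance across samples (the usual probe-to-symbol convention)."""
    df = matrix.data
    if not df.index.duplicated().any():
        return ExpressionMatrix(df)
    variances = df.var(axis=1, ddof=1).to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(np.arange(len(df)), index=df.index)
    for _, positions in order.groupby(level=0, sort=False):
        pos = positions.to_numpy()
        keep[pos[np.argmax(variances[pos])]] = True
    collapsed = df.iloc[keep]
    # preserve first-occurrence gene order
    first_order = list(dict.fromkeys(df.index))
    collapsed = collapsed.loc[first_order]
    return ExpressionMatrix(collapsed)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the mean across samples of the sorted value vectors;
    each sample's values are replaced by the reference values at their ranks,
    ties receiving the mean of the reference values they span.  This is the
    deterministic quantile member of the between-array normalization family.
    """
    df = matrix.data
    n_genes, n_samples = df.shape
    if n_samples < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        return ExpressionMatrix(df)
    vals = df.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = np.empty(n_genes)
        start = 0
        while start < n_genes:
            stop = start
            while stop + 1 < n_genes and sorted_col[stop + 1] == sorted_col[start]:
                stop += 1
            # tied block occupies reference slots start..stop -> mean of them
            assigned[start : stop + 1] = reference[start : stop + 1].mean()
            start = stop + 1
        out[order, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))
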