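"""Expression matrix I/O and per-sample rank normalization.

Correlation-based network screening downstream works on within-sample
ranks rather than raw intensities: ranking each array separately removes
platform- and tissue-dependent dynamic range, so samples from different
experiments live on a common dimensionless scale.  Each sample column is
converted to ranks (ascending: the most highly expressed gene gets the
largest rank) and then standardized to a z-score using the mean and
population standard deviation of that column's rank vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "RankNormalizedMatrix",
    "read_expression",
    "rank_normalize",
]

_TIE_METHODS = ("average", "min", "max")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values for one tissue with condition labels.

    Parameters
    ----------
    values
        DataFrame with unique gene symbols as the index and sample IDs as
        columns; entries are raw expression in arbitrary units.
    condition_of
        Mapping from sample ID to condition label.  Exactly two distinct
        labels must occur and each must cover at least three samples, the
        minimum for a meaningful rank correlation.
    tissue
        Free-text tissue label.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    tissue: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dupes}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        conds = sorted({self.condition_of[s] for s in self.values.columns})
        if len(conds) != 2:
            raise ValueError(
                f"expected exactly 2 condition labels, got {len(conds)}: {conds}"
            )
        for cond in conds:
            n = sum(
                1 for s in self.values.columns if self.condition_of[s] == cond
            )
            if n < 3:
                raise ValueError(
                    f"condition {cond!r} has {n} samples; need >= 3"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> tuple[str, str]:
        """The two condition labels, sorted."""
        return tuple(sorted({self.condition_of[s] for s in self.samples}))

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of[s] == condition]


@dataclass
class RankNormalizedMatrix:
    """Per-sample normalized rank z-scores, same shape as the source matrix.

    Every column has mean 0 and population standard deviation 1; within a
    column the ordering of the z-scores reproduces the ordering of the raw
    expression values.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    tissue: str = ""
    tie_method: str = "average"
    #: standard-deviation convention used in the z-score (recorded so output
    #: files are self-describing; "population" divides by n).
    sd_convention: str = "population"

    genes = ExpressionMatrix.genes
    samples = ExpressionMatrix.samples
    conditions = ExpressionMatrix.conditions
    samples_in = ExpressionMatrix.samples_in


def read_expression(
    matrix_path, metadata_path, tissue: str | None = None
) -> ExpressionMatrix:
    """Read a TSV expression matrix plus a sample-metadata table.

    The matrix has a header row of sample IDs and gene symbols in the first
    column.  The metadata TSV needs columns ``sample_id`` and ``condition``
    (an optional ``tissue`` column supplies the tissue label unless one is
    given explicitly).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    condition_of = dict(zip(meta["sample_id"], meta["condition"]))

    # locate non-numeric cells before the dtype coercion hides them
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric expression value at gene {gene!r}, sample {sample!r}"
        )

    if tissue is None:
        tissue = meta["tissue"].iloc[0] if "tissue" in meta.columns else ""
    return ExpressionMatrix(numeric.astype(float), condition_of, tissue)


def rank_normalize(
    m: ExpressionMatrix, tie_method: str = "average"
) -> RankNormalizedMatrix:
    """Replace each sample column by standardized within-sample ranks.

    Ranks are assigned ascending over all genes in the column (largest
    expression gets the largest rank), ties resolved by ``tie_method``;
    the column is then centred and scaled by the mean and population
    standard deviation of its rank vector: ``z = (rank - mu) / sigma``.

    Raises
    ------
    ValueError
        If a sample column is constant (sigma of the ranks is 0) or
        ``tie_method`` is not one of average, min, max.
    """
    if tie_method not in _TIE_METHODS:
        raise ValueError(
            f"tie_method must be one of {_TIE_METHODS}, got {tie_method!r}"
        )
    x = m.values.to_numpy(dtype=float)
    ranks = rankdata(x, method=tie_method, axis=0).astype(float)
    mu = ranks.mean(axis=0)
    sigma = ranks.std(axis=0)  # population sd: the column IS the population
    flat = np.flatnonzero(sigma == 0)
    if flat.size:
        raise ValueError(
            f"sample {m.samples[flat[0]]!r} has all-identical values; "
            "rank z-score is undefined"
        )
    z = (ranks - mu) / sigma
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return RankNormalizedMatrix(
        out, dict(m.condition_of), m.tissue, tie_method=tie_method
    )
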