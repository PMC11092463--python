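"""Tabular containers and their on-disk formats.

Cells and samples are carried as pandas DataFrames with documented column
schemas; per-sample category counts are wrapped in :class:`CompositionMatrix`
which fixes the sample/category ordering and round-trips to MatrixMarket
(with plain-text index sidecars) or wide TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: canonical columns of a cell table
CELL_COLUMNS = [
    "cell_id",
    "sample_id",
    "true_label",
    "label_source_1",
    "label_source_2",
    "label_source_3",
    "label_source_4",
    "consensus_label",
    "confidence_tier",
    "is_immune",
]

#: canonical columns of a sample table
SAMPLE_COLUMNS = [
    "sample_id",
    "dataset_id",
    "tissue_harmonised",
    "age_days",
    "sex",
    "ethnicity",
    "assay",
    "is_primary",
    "is_healthy",
    "n_cells",
]


@dataclass
class CompositionMatrix:
    """Integer counts of cells per sample (rows) and category (columns).

    The two-category immune/non-immune cellularity case is the K=2 instance
    of the same container.
    """

    counts: pd.DataFrame  # index: sample_id, columns: category names

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def proportions(self, pseudocount: float = 0.0) -> pd.DataFrame:
        y = self.counts.to_numpy(dtype=float) + pseudocount
        p = y / y.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=self.counts.index, columns=self.counts.columns)

    # ---- persistence -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompositionMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="sample_id")
        counts.index.name = None
        return cls(counts)

    def to_mtx(self, prefix: str | Path) -> None:
        """Write counts as <prefix>.mtx with .samples/.categories sidecars."""
        prefix = Path(prefix)
        mat = scipy.sparse.csr_matrix(self.counts.to_numpy())
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), mat)
        prefix.with_suffix(".samples.txt").write_text(
            "\n".join(map(str, self.counts.index)) + "\n"
        )
        prefix.with_suffix(".categories.txt").write_text(
            "\n".join(map(str, self.counts.columns)) + "\n"
        )

    @classmethod
    def from_mtx(cls, prefix: str | Path) -> "CompositionMatrix":
        prefix = Path(prefix)
        mat = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
        samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
        categories = prefix.with_suffix(".categories.txt").read_text().splitlines()
        return cls(pd.DataFrame(mat, index=samples, columns=categories))
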