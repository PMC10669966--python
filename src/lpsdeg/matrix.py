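"""Gene-by-sample count matrix with subtype labels.

The pipeline's main carrier. Counts are non-negative integers with genes on
rows and samples on columns; every sample carries a group (subtype) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus a sample -> subtype mapping.

    Parameters
    ----------
    counts:
        DataFrame with gene ids as index and sample ids as columns.
        Values must be non-negative integers.
    groups:
        Series indexed by sample id giving the subtype label of each sample.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        # keep only labels for present samples, in column order
        self.groups = self.groups.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.groups)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.groups)

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        meta = pd.DataFrame(
            {"sample": self.sample_ids, "subtype": self.groups.to_numpy()}
        )
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        groups = pd.Series(
            meta["subtype"].to_numpy(), index=meta["sample"].astype(str)
        )
        counts.columns = counts.columns.astype(str)
        return cls(counts, groups)
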