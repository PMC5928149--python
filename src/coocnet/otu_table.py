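"""OTU count tables and the classic tab-separated on-disk dialect.

The table is the universal input of the pipeline: an integer matrix of
sequencing read counts with samples as rows and OTUs (97%-identity 16S
clusters) as columns, plus optional per-sample metadata such as the host
developmental stage (larva / juvenile / adult), treatment and time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "read_otu_table_tsv", "write_otu_table_tsv",
           "read_sample_metadata_tsv", "write_sample_metadata_tsv"]


@dataclass
class OtuTable:
    """Integer read counts per (sample, OTU) with optional sample metadata.

    Parameters
    ----------
    counts
        ``(n_samples, n_otus)`` array of non-negative integers.
    otu_ids, sample_ids
        Unique string identifiers for columns and rows respectively.
    metadata
        Optional DataFrame indexed by sample id; the column ``"stage"``
        is recognised throughout the pipeline.
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (samples x OTUs) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        ns, no = self.counts.shape
        if len(self.otu_ids) != no:
            raise ValueError(f"{len(self.otu_ids)} otu_ids for {no} columns")
        if len(self.sample_ids) != ns:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {ns} rows")
        if len(set(self.otu_ids)) != no:
            raise ValueError("otu_ids must be unique")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("sample_ids must be unique")
        row_tot = self.counts.sum(axis=1)
        if np.any(row_tot == 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(row_tot == 0)]
            raise ValueError(f"samples with zero total reads: {bad}")
        if self.metadata is not None:
            missing = set(self.sample_ids) - set(map(str, self.metadata.index))
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)}")
            self.metadata = self.metadata.loc[self.sample_ids]

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_stage(self) -> np.ndarray | None:
        if self.metadata is not None and "stage" in self.metadata.columns:
            return self.metadata["stage"].to_numpy()
        return None

    def otu_totals(self) -> np.ndarray:
        """Total reads per OTU summed over all samples."""
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """Row-closed fractions (each sample sums to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def select_otus(self, keep: np.ndarray) -> "OtuTable":
        """New table restricted to the OTU columns in boolean/index ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            counts=self.counts[:, keep],
            otu_ids=[self.otu_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            metadata=None if self.metadata is None else self.metadata.copy(),
        )

    def select_samples(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.sample_ids[i] for i in keep]
        return OtuTable(
            counts=self.counts[keep, :],
            otu_ids=list(self.otu_ids),
            sample_ids=ids,
            metadata=None if self.metadata is None else self.metadata.loc[ids],
        )

    def subset_stage(self, stage: str) -> "OtuTable":
        st = self.sample_stage
        if st is None:
            raise ValueError("table has no 'stage' metadata column")
        return self.select_samples(st == stage)

    def to_frame(self) -> pd.DataFrame:
        """OTUs x samples DataFrame in the classic orientation."""
        return pd.DataFrame(self.counts.T, index=self.otu_ids,
                            columns=self.sample_ids)


def write_otu_table_tsv(table: OtuTable, path: str | Path) -> None:
    """Write the classic tab-separated OTU table (rows = OTUs).

    The header line starts with ``#OTU ID`` followed by sample ids, the
    layout QIIME and most downstream tools exchange.
    """
    df = table.to_frame()
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
        df.to_csv(fh, sep="\t", header=False)


def read_otu_table_tsv(path: str | Path,
                       metadata: pd.DataFrame | None = None) -> OtuTable:
    """Read a classic OTU-table TSV (leading ``#OTU ID`` column, rows = OTUs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    # the header may be the commented '#OTU ID' line: pandas keeps it as a column name
    return OtuTable(
        counts=df.to_numpy().T.astype(np.int64),
        otu_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        metadata=metadata,
    )


def write_sample_metadata_tsv(table: OtuTable, path: str | Path) -> None:
    if table.metadata is None:
        raise ValueError("table has no metadata")
    table.metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
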