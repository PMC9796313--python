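"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered time-point labels of the treatment design
#: (untreated baseline, 30 min and 3 h after addition of the macrolide).
TIME_POINTS: tuple[str, str, str] = ("0", "0.5h", "3h")

#: Accepted spellings for each canonical time label.
_TIME_ALIASES = {
    "0": "0", "0h": "0", "0.0": "0", "t0": "0",
    "0.5h": "0.5h", "0.5": "0.5h", "30min": "0.5h", "30m": "0.5h",
    "3h": "3h", "3": "3h", "3.0": "3h", "180min": "3h",
}


class StructuralError(ValueError):
    """Raised when an input file or table violates its structural contract."""


def canonical_time(label: object) -> str:
    """Map a time label to one of the canonical labels in :data:`TIME_POINTS`."""
    key = str(label).strip().lower()
    try:
        return _TIME_ALIASES[key]
    except KeyError:
        raise StructuralError(
            f"unrecognized time point {label!r}; expected one of {TIME_POINTS}"
        ) from None


@dataclass
class CountExperiment:
    """A gene x sample matrix of read counts plus the sample design.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as rows (unique index), samples as columns.
    design
        DataFrame indexed by sample id with columns ``time`` (one of
        :data:`TIME_POINTS`) and ``replicate``.
    gene_lengths
        Optional Series of exon-union lengths in bp, indexed by gene id.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    gene_lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate gene ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise StructuralError("counts must be numeric integers")
        if np.any(~np.isfinite(vals.astype(float))) or np.any(vals.astype(float) % 1 != 0):
            raise StructuralError("counts must be integers")
        if (vals < 0).any():
            raise StructuralError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

        missing = {"time", "replicate"} - set(self.design.columns)
        if missing:
            raise StructuralError(f"design lacks columns: {sorted(missing)}")
        in_counts = set(self.counts.columns)
        in_design = set(self.design.index)
        if in_counts != in_design:
            raise StructuralError(
                f"sample mismatch: only in counts {sorted(in_counts - in_design)[:5]}, "
                f"only in design {sorted(in_design - in_counts)[:5]}"
            )
        self.design = self.design.copy()
        self.design["time"] = [canonical_time(t) for t in self.design["time"]]
        # align design rows to column order of the matrix
        self.design = self.design.loc[list(self.counts.columns)]

        if self.gene_lengths is not None:
            gl = pd.Series(self.gene_lengths, dtype=float)
            if (gl < 1).any():
                raise StructuralError("gene lengths must be >= 1 bp")
            self.gene_lengths = gl

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total read count per sample."""
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, gene_ids) -> "CountExperiment":
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.reindex(gene_ids)
        return CountExperiment(self.counts.loc[gene_ids], self.design.copy(), lengths)
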