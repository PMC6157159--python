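"""Methylation beta-value matrices and their TSV representation.

Beta values are methylated-signal proportions in [0, 1], one matrix per
treatment phase (pre / post).  Values are stored as a samples x sites
pandas DataFrame (NaN = missing) with a separate per-site annotation table
(chromosome and 1-based position) needed by the cis-meQTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "read_methylation", "write_methylation"]


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites beta values plus site coordinates.

    ``values``: DataFrame, index = sample ids, columns = site ids.
    ``sites``: DataFrame indexed by site id with columns ``chrom``, ``pos``.
    ``phase``: 'pre' or 'post'.
    """

    values: pd.DataFrame = field(repr=False)
    sites: pd.DataFrame = field(repr=False)
    phase: str = "pre"

    def __post_init__(self) -> None:
        if self.phase not in {"pre", "post"}:
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated site_id in methylation matrix")
        missing = set(self.values.columns) - set(self.sites.index)
        if missing:
            raise ValueError(f"{len(missing)} sites lack annotation (e.g. {sorted(missing)[0]!r})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict_samples(self, sample_ids: list[str]) -> "MethylationMatrix":
        keep = [s for s in self.values.index if s in set(sample_ids)]
        return MethylationMatrix(self.values.loc[keep], self.sites, self.phase)


def write_methylation(m: MethylationMatrix, values_path: str, sites_path: str) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="sample_id", float_format="%.6g")
    ann = m.sites.loc[m.site_ids]
    ann.to_csv(sites_path, sep="\t", index_label="site_id")


def read_methylation(values_path: str, sites_path: str, phase: str) -> MethylationMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    sites = pd.read_csv(sites_path, sep="\t", index_col=0)
    sites.index = sites.index.astype(str)
    return MethylationMatrix(values, sites, phase)
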