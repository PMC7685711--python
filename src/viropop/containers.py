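"""In-memory containers shared across the package.

A cohort lives in two pandas objects: a sample table (one row per fly)
and a :class:`GenotypeMatrix` holding within-host derived-allele
frequencies for the infected samples together with locus annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = (
    "sample_id", "species", "population", "sex", "wolbachia",
    "collection_date", "infected", "log10_titer",
)

LOCUS_COLUMNS = ("position", "annotation", "gene", "focal", "focal_order")

#: within-host frequency at or above which the sample's consensus allele
#: is the derived one (haploid consensus calls)
CONSENSUS_THRESHOLD = 0.5


@dataclass
class GenotypeMatrix:
    """Samples x loci within-host derived-allele frequencies plus metadata.

    ``freq`` is indexed by sample_id with one column per locus_id, values
    in [0, 1].  ``loci`` is indexed by locus_id (same order as the
    columns of ``freq``) with 1-based genome ``position`` (strictly
    increasing), ``annotation`` class, ``gene`` label, a boolean
    ``focal`` flag and a ``focal_order`` index for focal loci.
    """

    freq: pd.DataFrame
    loci: pd.DataFrame

    def validate(self) -> None:
        if list(self.freq.columns) != list(self.loci.index):
            raise ValueError("freq columns and loci index must match in order")
        if len(self.loci) > 0:
            pos = self.loci["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("locus positions must be strictly increasing")
            vals = self.freq.to_numpy(dtype=float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.freq)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def consensus(self) -> pd.DataFrame:
        """Haploid 0/1 consensus calls (derived iff frequency >= 0.5)."""
        return (self.freq >= CONSENSUS_THRESHOLD).astype(np.int8)

    def focal_loci(self) -> list[str]:
        if "focal" not in self.loci.columns:
            return []
        return list(self.loci.index[self.loci["focal"].astype(bool)])

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        locus_ids = list(locus_ids)
        return GenotypeMatrix(
            freq=self.freq.loc[:, locus_ids].copy(),
            loci=self.loci.loc[locus_ids].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            freq=self.freq.loc[list(sample_ids)].copy(),
            loci=self.loci.copy(),
        )
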