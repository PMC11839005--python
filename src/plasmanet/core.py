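"""Shared in-memory containers.

Conventions used throughout the package:

* sample-major orientation in memory — matrices are ``pandas.DataFrame``
  objects with samples as rows, even though the on-disk TSV conventions
  (dosage "-012" matrices, expression tables) are feature-major;
* genomic positions are 1-based inclusive internally (dbSNP/GTF style);
  BED input is converted on read;
* ``FeatureMatrix`` is an alias for a samples x features ``DataFrame``
  holding tissue expression or plasma protein (NPX-like) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: samples x features real-valued matrix (tissue expression, plasma proteins)
FeatureMatrix = pd.DataFrame


@dataclass
class GenotypeMatrix:
    """Additive-dosage genotypes with per-SNP metadata.

    Parameters
    ----------
    dosages
        samples x SNPs matrix of allele dosages; simulated data is strictly
        in {0, 1, 2}, real dosage data may be fractional in [0, 2].
    snp_info
        per-SNP table indexed by SNP id with columns ``chrom`` and ``pos``
        (1-based); a ``maf`` column is added lazily by :meth:`maf`.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.snp_info is None:
            self.snp_info = pd.DataFrame(
                {"chrom": "1", "pos": np.arange(1, self.dosages.shape[1] + 1)},
                index=self.dosages.columns,
            )
        if not self.dosages.columns.equals(self.snp_info.index):
            raise ValueError("dosage columns and snp_info index must match")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate SNP identifiers")
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP: min(p, 1-p) with p = mean/2."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = pd.Index(snp_ids)
        return GenotypeMatrix(
            dosages=self.dosages.loc[:, snp_ids],
            snp_info=self.snp_info.loc[snp_ids],
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[pd.Index(sample_ids)],
            snp_info=self.snp_info,
        )
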