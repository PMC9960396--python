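"""Abundance quantification: RPKM, retention filtering, detection, downsampling.

The abundance unit throughout is RPKM (reads mapped per kilobase of marker
gene per million library reads). Species enter downstream analyses only if
they achieve 100% marker base coverage at >=2-fold mean depth in at least one
sample, a one-time retention rule that removes low-coverage spurious taxa.
"detected" in a given sample means at least one mapped read (RPKM > 0);
detection fractions are computed over non-missing months only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SpeciesCountTable


@dataclass
class AbundanceTable:
    rpkm: pd.DataFrame  # species x sample
    rel_abund: pd.DataFrame  # species x sample, columns sum to 1 (or 0)
    retained_species: pd.Index
    fraction_label: str = ""


def rpkm(count, gene_length, library_size):
    """RPKM = count / ((gene_length/1e3) * (library_size/1e6)); vectorised."""
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(gene_length <= 0):
        raise ValueError("gene_length must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) / ((gene_length / 1e3) * (library_size / 1e6))


def rpkm_table(table: SpeciesCountTable) -> pd.DataFrame:
    vals = rpkm(
        table.counts.to_numpy(),
        table.gene_length.loc[table.species].to_numpy()[:, None],
        table.library_size.loc[table.samples].to_numpy()[None, :],
    )
    return pd.DataFrame(vals, index=table.species, columns=table.samples)


def retention_filter(table: SpeciesCountTable) -> pd.Index:
    """Species with 100% base coverage and >=2-fold mean depth in >=1 sample."""
    ok = (table.base_coverage.to_numpy() >= 1.0) & (table.mean_depth.to_numpy() >= 2.0)
    return table.species[ok.any(axis=1)]


def downsample_counts(counts: pd.DataFrame, factor: float = 5.0) -> pd.DataFrame:
    """Divide counts by ``factor``; values falling below 1 are reassigned 0.

    Fractional values >= 1 are retained (only values below 1 are zeroed).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    down = counts.astype(float) / factor
    return down.where(down >= 1.0, 0.0)


def downsample_table(table: SpeciesCountTable, factor: float = 5.0) -> SpeciesCountTable:
    """Downsampled copy of a count table with depth/coverage rescaled to match."""
    down = downsample_counts(table.counts, factor)
    scale = np.divide(
        down.to_numpy(),
        table.counts.to_numpy(),
        out=np.zeros_like(down.to_numpy(), dtype=float),
        where=table.counts.to_numpy() > 0,
    )
    return SpeciesCountTable(
        counts=down,
        gene_length=table.gene_length,
        library_size=table.library_size / factor,
        base_coverage=table.base_coverage,
        mean_depth=table.mean_depth * scale,
        fraction_label=table.fraction_label,
    )


def detection_mask(rpkm_df: pd.DataFrame) -> pd.DataFrame:
    """Boolean species x sample matrix: detected iff RPKM > 0."""
    return rpkm_df > 0


def detection_fraction(rpkm_df: pd.DataFrame) -> pd.Series:
    """Per-species fraction of (non-missing) samples in which it was detected.

    Missing months are represented as absent columns, so the denominator is
    simply the number of columns.
    """
    if rpkm_df.shape[1] == 0:
        return pd.Series(0.0, index=rpkm_df.index)
    return detection_mask(rpkm_df).sum(axis=1) / rpkm_df.shape[1]


def relative_abundance(rpkm_df: pd.DataFrame) -> pd.DataFrame:
    """Column-normalised RPKM; all-zero samples stay all-zero."""
    colsum = rpkm_df.sum(axis=0)
    out = rpkm_df.divide(colsum.where(colsum > 0, np.nan), axis=1)
    return out.fillna(0.0)


def abundance_table(table: SpeciesCountTable, retained_only: bool = True) -> AbundanceTable:
    """RPKM + relative abundance, restricted to retained species by default."""
    retained = retention_filter(table)
    r = rpkm_table(table)
    if retained_only:
        r = r.loc[retained]
    return AbundanceTable(
        rpkm=r,
        rel_abund=relative_abundance(r),
        retained_species=retained,
        fraction_label=table.fraction_label,
    )
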