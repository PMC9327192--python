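"""Coverage-normalized relative abundance.

The core statistic is the coverage-normalized gene relative abundance

    a_i = b_i / sum_j b_j,   b_i = X_i / L_i,

where X_i is the number of reads mapped to gene i and L_i its length:
each gene's per-base coverage, normalized over the whole gene catalogue
of a sample.  Taxon abundances are sums of their genes' a_i; the
fraction of cells carrying a functional gene family is the family's
abundance divided by that of a single-copy marker (recA for bacteria,
ACTB for eukaryotes); and metagenome-assembled genome (MAG) abundances
are mean nucleotide coverage divided by the sample's genome equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EmptySampleError",
    "DuplicateAssignmentError",
    "ExcludedMagError",
    "UndefinedNormalizationError",
    "MagRecord",
    "MarkerNormalization",
    "gene_relative_abundance",
    "taxon_relative_abundance",
    "marker_normalized_fraction",
    "genome_equivalents",
    "mag_relative_abundance",
]

MAG_CONTAMINATION_MAX_PCT = 5.0  # exclusive upper bound for inclusion


class EmptySampleError(ValueError):
    """No mapped reads in the requested sample."""


class DuplicateAssignmentError(ValueError):
    """A gene is assigned to more than one taxon."""


class ExcludedMagError(ValueError):
    """MAG fails the contamination gate."""


class UndefinedNormalizationError(ValueError):
    """Marker relative abundance is zero; carrier fraction undefined."""


def gene_relative_abundance(
    hit_table: pd.DataFrame, sample: str | None = None
) -> pd.Series:
    """Per-gene relative abundance of one sample's gene hit table.

    ``hit_table`` needs columns ``gene_id``, ``length_nt`` and
    ``mapped_reads`` (plus ``sample_id`` if ``sample`` is given to select
    one sample from a multi-sample table).  Genes with zero reads are
    retained with abundance 0.  Raises :class:`EmptySampleError` when no
    gene has any reads, and ``ValueError`` on non-positive lengths,
    negative counts or duplicate gene ids.
    """
    df = hit_table
    if sample is not None:
        df = df[df["sample_id"] == sample]
    if df.empty:
        raise EmptySampleError(f"no rows for sample {sample!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene_id must be unique within a sample")
    lengths = df["length_nt"].to_numpy(dtype=float)
    reads = df["mapped_reads"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(reads < 0):
        raise ValueError("mapped_reads must be >= 0")
    coverage = reads / lengths
    total = coverage.sum()
    if total <= 0:
        raise EmptySampleError("all genes have zero mapped reads")
    return pd.Series(coverage / total, index=pd.Index(df["gene_id"], name="gene_id"))


def taxon_relative_abundance(
    ra_table: pd.Series, taxon_map: pd.Series | dict | pd.DataFrame
) -> pd.Series:
    """Sum gene abundances into taxon abundances.

    ``taxon_map`` maps gene_id -> taxon; genes absent from the map are
    pooled under ``"unassigned"``.  A gene mapped to two different taxa
    raises :class:`DuplicateAssignmentError`.  The output sums to 1
    whenever the input does.
    """
    if isinstance(taxon_map, pd.DataFrame):
        dup = taxon_map.drop_duplicates()
        if dup["gene_id"].duplicated().any():
            offender = dup.loc[dup["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DuplicateAssignmentError(f"gene {offender!r} mapped to two taxa")
        mapping = dict(zip(dup["gene_id"], dup["taxon"]))
    else:
        mapping = dict(taxon_map)
    taxa = ra_table.index.map(lambda g: mapping.get(g, "unassigned"))
    out = ra_table.groupby(taxa).sum()
    out.index.name = "taxon"
    return out


@dataclass
class MarkerNormalization:
    """Carrier fraction with a flag for values exceeding one genome copy."""

    fraction: float
    multi_copy: bool


def marker_normalized_fraction(
    gene_family_ra: float, marker_ra: float
) -> MarkerNormalization:
    """Fraction of cells carrying a gene family.

    Divides the family's relative abundance by that of a single-copy
    marker from the same sample (recA for bacteria, ACTB for algae).
    Values above 1 are legitimate for multi-copy families and are
    flagged rather than clipped.
    """
    if marker_ra < 0 or gene_family_ra < 0:
        raise ValueError("relative abundances must be >= 0")
    if marker_ra == 0:
        raise UndefinedNormalizationError("marker relative abundance is zero")
    fraction = gene_family_ra / marker_ra
    return MarkerNormalization(fraction=float(fraction), multi_copy=fraction > 1.0)


def genome_equivalents(total_mapped_bases: float, average_genome_size_bp: float) -> float:
    """Number of genomes sequenced in a metagenome.

    Simple ratio estimator: total mapped bases over the community's
    average genome size (supplied by the caller or known in synthetic
    data).
    """
    if total_mapped_bases <= 0 or average_genome_size_bp <= 0:
        raise ValueError("inputs must be positive")
    return float(total_mapped_bases / average_genome_size_bp)


@dataclass
class MagRecord:
    """Per-MAG coverage and quality summary."""

    mag_id: str
    mag_length: int
    summed_nucleotide_coverage: dict[str, float]
    completeness: float
    contamination: float


def mag_relative_abundance(
    mag_record: MagRecord, sample: str, sample_genome_equivalents: float
) -> float:
    """Relative abundance of a MAG: mean coverage / genome equivalents.

    MAGs with contamination at or above 5% are excluded from analysis
    (:class:`ExcludedMagError`).
    """
    if mag_record.contamination >= MAG_CONTAMINATION_MAX_PCT:
        raise ExcludedMagError(
            f"MAG {mag_record.mag_id}: contamination "
            f"{mag_record.contamination}% >= {MAG_CONTAMINATION_MAX_PCT}%"
        )
    if sample_genome_equivalents <= 0:
        raise ValueError("genome equivalents must be positive")
    if mag_record.mag_length <= 0:
        raise ValueError("MAG length must be positive")
    coverage = mag_record.summed_nucleotide_coverage[sample] / mag_record.mag_length
    return float(coverage / sample_genome_equivalents)
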