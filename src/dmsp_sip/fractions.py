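"""Density-gradient fraction handling.

After isopycnic ultracentrifugation, a CsCl gradient is dripped into
fractions whose density is read by refractometry and whose DNA content is
fluorometrically quantified.  This module converts refractive index to
buoyant density, partitions the fractions of a sample into heavy
(isotopically labelled) and light (unlabelled) sets, and reconstructs the
unfractionated community in silico by mass-weighted mixing of the heavy
and light relative-abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "RI_SLOPE",
    "RI_OFFSET",
    "RI_RANGE",
    "THETA_HEAVY_DEFAULT",
    "THETA_LIGHT_DEFAULT",
    "FractionProfile",
    "HeavyLightPartition",
    "PartitionUndefinedError",
    "EmptyPartitionError",
    "density_from_ri",
    "ri_from_density",
    "partition_fractions",
    "reconstruct_total",
    "pool_replicate_tables",
    "profiles_to_frame",
    "write_partition",
    "read_fractions",
]

# Linear refractive-index -> density relation for CsCl at 25 degC.
RI_SLOPE = 10.8601  # g/mL per RI unit
RI_OFFSET = 13.4974  # g/mL
RI_RANGE = (1.34, 1.42)

# Default density cut-offs for the heavy/light split (g/mL).  Fractions
# between the two are excluded from downstream analysis, mirroring the
# practice of sequencing only clearly-separated gradient regions.
THETA_HEAVY_DEFAULT = 1.725
THETA_LIGHT_DEFAULT = 1.715


class PartitionUndefinedError(ValueError):
    """The requested partition rule cannot be applied to this profile."""


class EmptyPartitionError(ValueError):
    """Both heavy and light sets carry zero DNA mass."""


def density_from_ri(refractive_index, slope: float = RI_SLOPE, offset: float = RI_OFFSET):
    """Convert refractive index to CsCl buoyant density (g/mL).

    Uses the linear refractometry relation ``rho = slope * RI - offset``
    with 25 degC CsCl defaults.  Accepts scalars or arrays; RI outside
    [1.34, 1.42] raises ``ValueError``.
    """
    ri = np.asarray(refractive_index, dtype=float)
    lo, hi = RI_RANGE
    if np.any(ri < lo) or np.any(ri > hi):
        raise ValueError(f"refractive index outside plausible range {RI_RANGE}")
    rho = slope * ri - offset
    return float(rho) if np.isscalar(refractive_index) else rho


def ri_from_density(density, slope: float = RI_SLOPE, offset: float = RI_OFFSET):
    """Inverse of :func:`density_from_ri`."""
    rho = np.asarray(density, dtype=float)
    ri = (rho + offset) / slope
    return float(ri) if np.isscalar(density) else ri


@dataclass
class FractionProfile:
    """One gradient fraction: identity, refractometry reading and DNA yield."""

    sample_id: str
    fraction_id: str
    refractive_index: float
    dna_ng: float
    density: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dna_ng < 0:
            raise ValueError("dna_ng must be non-negative")
        if self.density is None:
            self.density = density_from_ri(self.refractive_index)


@dataclass
class HeavyLightPartition:
    """Assignment of a sample's fractions to heavy / light / excluded sets."""

    heavy: tuple[str, ...]
    light: tuple[str, ...]
    dna_mass_heavy: float
    dna_mass_light: float
    excluded: tuple[str, ...] = ()
    rule: str = "density_threshold"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.heavy) & set(self.light):
            raise ValueError("heavy and light sets must be disjoint")


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima, endpoints included (find_peaks drops them)."""
    padded = np.concatenate([[-np.inf], values, [-np.inf]])
    peaks, _ = find_peaks(padded)
    return peaks - 1


def partition_fractions(
    profiles: list[FractionProfile],
    rule: str = "density_threshold",
    theta_heavy: float = THETA_HEAVY_DEFAULT,
    theta_light: float = THETA_LIGHT_DEFAULT,
) -> HeavyLightPartition:
    """Split a sample's fractions into heavy and light DNA pools.

    Two rules are supported.  ``"density_threshold"`` (default) assigns
    fractions with density >= ``theta_heavy`` to the heavy set, those with
    density <= ``theta_light`` to the light set, and excludes the band in
    between.  ``"bimodal_valley"`` locates the two largest local maxima of
    the DNA-vs-density curve and splits at the minimum between them; it
    raises :class:`PartitionUndefinedError` on unimodal profiles so the
    caller can fall back to thresholds.

    Requires at least 4 DNA-bearing fractions.
    """
    if sum(p.dna_ng > 0 for p in profiles) < 4:
        raise ValueError("need at least 4 fractions with DNA > 0 to partition")
    ordered = sorted(profiles, key=lambda p: p.density)
    dens = np.array([p.density for p in ordered])
    dna = np.array([p.dna_ng for p in ordered])
    ids = [p.fraction_id for p in ordered]

    if rule == "density_threshold":
        if theta_heavy < theta_light:
            raise ValueError("theta_heavy must be >= theta_light")
        heavy = [i for i, d in zip(ids, dens) if d >= theta_heavy]
        # heavy takes precedence when theta_heavy == theta_light
        light = [i for i, d in zip(ids, dens) if d <= theta_light and d < theta_heavy]
        params = {"theta_heavy": theta_heavy, "theta_light": theta_light}
    elif rule == "bimodal_valley":
        peaks = _local_maxima(dna)
        peaks = peaks[dna[peaks] > 0]
        if len(peaks) < 2:
            raise PartitionUndefinedError("DNA profile is not bimodal")
        top_two = sorted(peaks[np.argsort(dna[peaks])[-2:]])
        lo, hi = top_two
        valley = lo + int(np.argmin(dna[lo : hi + 1]))
        heavy = ids[valley + 1 :]
        light = ids[:valley]
        params = {"valley_density": float(dens[valley])}
    else:
        raise ValueError(f"unknown partition rule {rule!r}")

    assigned = set(heavy) | set(light)
    excluded = [i for i in ids if i not in assigned]
    mass = dict(zip(ids, dna))
    return HeavyLightPartition(
        heavy=tuple(heavy),
        light=tuple(light),
        excluded=tuple(excluded),
        dna_mass_heavy=float(sum(mass[i] for i in heavy)),
        dna_mass_light=float(sum(mass[i] for i in light)),
        rule=rule,
        params=params,
    )


def reconstruct_total(
    ra_heavy: pd.Series, ra_light: pd.Series, partition: HeavyLightPartition
) -> pd.Series:
    """Reconstruct the unfractionated community from heavy and light tables.

    The total relative abundance of each entity is the mixture
    ``(m_H * a_heavy + m_L * a_light) / (m_H + m_L)`` where the weights are
    the DNA masses of the heavy and light fraction sets.  Entities missing
    from one table are treated as zero there.
    """
    m_h, m_l = partition.dna_mass_heavy, partition.dna_mass_light
    if m_h + m_l <= 0:
        raise EmptyPartitionError("partition carries no DNA mass")
    idx = ra_heavy.index.union(ra_light.index)
    h = ra_heavy.reindex(idx, fill_value=0.0)
    l = ra_light.reindex(idx, fill_value=0.0)
    return (m_h * h + m_l * l) / (m_h + m_l)


def pool_replicate_tables(tables: list[pd.Series]) -> pd.Series:
    """Equal-mass merge of replicate relative-abundance tables.

    Models pooling biological replicates in equal proportions before
    sequencing; with normalized inputs this is the plain mean.
    """
    if not tables:
        raise ValueError("no tables to pool")
    idx = tables[0].index
    for t in tables[1:]:
        idx = idx.union(t.index)
    stacked = pd.concat([t.reindex(idx, fill_value=0.0) for t in tables], axis=1)
    return stacked.mean(axis=1)


def profiles_to_frame(profiles: list[FractionProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "fraction_id": [p.fraction_id for p in profiles],
            "refractive_index": [p.refractive_index for p in profiles],
            "density": [p.density for p in profiles],
            "dna_ng": [p.dna_ng for p in profiles],
        }
    )


def read_fractions(path) -> list[FractionProfile]:
    """Read a fractions.tsv written by the simulator or CLI."""
    df = pd.read_csv(path, sep="\t")
    return [
        FractionProfile(
            sample_id=str(r.sample_id),
            fraction_id=str(r.fraction_id),
            refractive_index=float(r.refractive_index),
            dna_ng=float(r.dna_ng),
        )
        for r in df.itertuples()
    ]


def write_partition(partition: HeavyLightPartition, sample_id: str, path) -> None:
    rows = (
        [(sample_id, f, "heavy") for f in partition.heavy]
        + [(sample_id, f, "light") for f in partition.light]
        + [(sample_id, f, "excluded") for f in partition.excluded]
    )
    pd.DataFrame(rows, columns=["sample_id", "fraction_id", "set"]).to_csv(
        path, sep="\t", index=False
    )
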