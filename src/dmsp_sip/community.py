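"""Synthetic DNA-SIP community generator.

Simulates the full chain of a stable-isotope-probing experiment with a
moiety-labelled substrate: a taxon community with distinct catabolic
phenotypes, a labelling incubation in which only substrate-carbon users
incorporate the heavy isotope, isopycnic density-gradient fractionation
with GC- and label-dependent buoyant density, and multinomial shotgun
read sampling of pooled fractions.  Every stochastic operation consumes
one explicit seeded :class:`numpy.random.Generator`, so identical seeds
give identical outputs.

The four phenotypes mirror the roles a moiety-labelled substrate can
distinguish:

``substrate_carbon_user``
    cleaves the substrate and assimilates the labelled moiety into new
    biomass (carries the *dddD* lyase cluster with its downstream route);
``moiety_gas_user``
    grows on the unlabelled volatile cleavage product (DMS) and therefore
    blooms without becoming isotopically heavy (carries *mtoX*);
``gene_carrier_nonuser``
    carries catabolic genes (*dmdA*, *dddP*) but does not use the
    substrate for carbon, so neither grows nor labels;
``nonuser``
    background community member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fractions import FractionProfile, ri_from_density

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "PHENOTYPES",
    "TaxonSpec",
    "LabelingScheme",
    "CommunityConfig",
    "GradientConfig",
    "IncubatedCommunity",
    "KineticParams",
    "EmptyPoolError",
    "sample_community",
    "simulate_incubation",
    "modal_density",
    "simulate_gradient",
    "simulate_gene_counts",
    "simulate_timecourse",
    "community_to_frame",
    "export_gene_fasta",
    "write_tables",
]

#: Natural abundance of carbon-13 (atom fraction).
NATURAL_13C_ABUNDANCE = 0.011

PHENOTYPES = (
    "substrate_carbon_user",
    "moiety_gas_user",
    "gene_carrier_nonuser",
    "nonuser",
)

# family -> (copies, gene length in nt).  Lengths are typical coding
# lengths; dddD is long (the protein exceeds 800 aa).
_TEMPLATES: dict[str, dict[str, tuple[int, int]]] = {
    "substrate_carbon_user": {
        "dddD": (1, 2700),
        "dddB": (1, 1500),
        "dddC": (1, 900),
        "dddT": (1, 1500),
        "prpE": (1, 1900),
        "acuI": (1, 1000),
        "recA": (1, 1060),
    },
    "moiety_gas_user": {"mtoX": (1, 1400), "recA": (1, 1060)},
    "gene_carrier_nonuser": {"dmdA": (1, 1100), "dddP": (1, 1300), "recA": (1, 1060)},
    "nonuser": {"recA": (1, 1060)},
}


class EmptyPoolError(ValueError):
    """A DNA pool with zero total mass cannot be sequenced."""


@dataclass
class TaxonSpec:
    """A simulated taxon: genomic properties, starting abundance and role."""

    name: str
    gc_fraction: float
    genome_length: int
    baseline_ra: float
    phenotype: str
    growth_factor: float
    gene_complement: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.baseline_ra < 0:
            raise ValueError("baseline_ra must be >= 0")
        if self.growth_factor < 0:
            raise ValueError("growth_factor must be >= 0")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.gene_complement.get("recA", (0, 0))[0] != 1:
            raise ValueError("every taxon must carry exactly one recA copy")


@dataclass
class LabelingScheme:
    """Which phenotypes incorporate the heavy isotope, and how strongly.

    ``atom_fraction_incorporated`` maps each phenotype to the 13C atom
    fraction of *newly synthesised* biomass carbon.  A 12C control scheme
    pins every phenotype at natural abundance.
    """

    substrate: str
    labeled_atoms_per_molecule: int
    is_control: bool
    atom_fraction_incorporated: dict[str, float]

    def __post_init__(self) -> None:
        for phen, f in self.atom_fraction_incorporated.items():
            if not NATURAL_13C_ABUNDANCE <= f <= 1.0:
                raise ValueError(
                    f"atom fraction for {phen!r} must be in "
                    f"[{NATURAL_13C_ABUNDANCE}, 1]"
                )
            if self.is_control and f != NATURAL_13C_ABUNDANCE:
                raise ValueError("control scheme must use natural abundance throughout")

    @classmethod
    def c13_propionate_dmsp(cls, incorporated: float = 0.8) -> "LabelingScheme":
        """13C3-propionate-labelled DMSP: only substrate-carbon users label.

        The three propionate carbons are fully labelled; DMS-moiety users
        and non-users receive only natural-abundance carbon.
        """
        return cls(
            substrate="13C3-propionate-DMSP",
            labeled_atoms_per_molecule=3,
            is_control=False,
            atom_fraction_incorporated={
                "substrate_carbon_user": incorporated,
                "moiety_gas_user": NATURAL_13C_ABUNDANCE,
                "gene_carrier_nonuser": NATURAL_13C_ABUNDANCE,
                "nonuser": NATURAL_13C_ABUNDANCE,
            },
        )

    @classmethod
    def c12_control(cls) -> "LabelingScheme":
        """Unlabelled-substrate control: nothing labels."""
        return cls(
            substrate="12C-DMSP",
            labeled_atoms_per_molecule=0,
            is_control=True,
            atom_fraction_incorporated={p: NATURAL_13C_ABUNDANCE for p in PHENOTYPES},
        )


@dataclass
class CommunityConfig:
    """Study conditions for community generation.

    Defaults emulate a coastal surface-seawater community amended with a
    large substrate pulse: degrader phenotypes are rare at T0 and bloom
    strongly during the incubation, while gene-carrying non-users and the
    background community do not grow.
    """

    phenotype_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "substrate_carbon_user": 0.05,
            "moiety_gas_user": 0.10,
            "gene_carrier_nonuser": 0.15,
            "nonuser": 0.70,
        }
    )
    dirichlet_alpha: float = 1.0
    #: Multiplier applied to the Dirichlet draw before renormalization;
    #: degraders start rare, as in natural seawater.
    baseline_scale: dict[str, float] = field(
        default_factory=lambda: {
            "substrate_carbon_user": 0.3,
            "moiety_gas_user": 0.1,
            "gene_carrier_nonuser": 1.0,
            "nonuser": 1.0,
        }
    )
    growth_factors: dict[str, float] = field(
        default_factory=lambda: {
            "substrate_carbon_user": 16.0,
            "moiety_gas_user": 16.0,
            "gene_carrier_nonuser": 1.0,
            "nonuser": 1.0,
        }
    )
    #: Detectability floor on the (scaled) baseline RA of designed
    #: degrader phenotypes: a degrader absent from the inoculum is not an
    #: informative benchmark of the classifier.
    min_phenotype_baseline: dict[str, float] = field(
        default_factory=lambda: {
            "substrate_carbon_user": 0.005,
            "moiety_gas_user": 0.005,
        }
    )
    gc_mean: float = 0.50
    gc_sd: float = 0.015
    gc_bounds: tuple[float, float] = (0.40, 0.60)
    genome_length_range: tuple[int, int] = (3_000_000, 6_000_000)
    total_dna_ng: float = 4000.0
    #: One catalogued background gene per this many bp of genome, so the
    #: per-taxon gene catalogue scales with genome size (microbial gene
    #: density is roughly constant); 0 disables background genes.
    background_gene_spacing_bp: int = 50_000
    background_gene_length_nt: int = 1000
    gene_templates: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {p: dict(t) for p, t in _TEMPLATES.items()}
    )


def _apportion(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n taxa to phenotypes."""
    raw = {p: q * n for p, q in proportions.items()}
    counts = {p: int(np.floor(v)) for p, v in raw.items()}
    short = n - sum(counts.values())
    for p in sorted(raw, key=lambda p: raw[p] - counts[p], reverse=True)[:short]:
        counts[p] += 1
    return counts


def sample_community(
    config: CommunityConfig | None = None, n_taxa: int = 20, seed: int = 0
) -> list[TaxonSpec]:
    """Draw a seeded community of ``n_taxa`` :class:`TaxonSpec` objects.

    Phenotype counts follow ``config.phenotype_proportions`` by
    largest-remainder apportionment; baseline relative abundances come
    from a symmetric Dirichlet, rescaled per phenotype and renormalized.
    """
    if n_taxa < 2:
        raise ValueError("a community needs at least 2 taxa")
    config = config or CommunityConfig()
    total = sum(config.phenotype_proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("phenotype proportions must sum to 1")
    rng = np.random.default_rng(seed)

    counts = _apportion(config.phenotype_proportions, n_taxa)
    phenotypes = [p for p in PHENOTYPES for _ in range(counts.get(p, 0))]

    raw = rng.dirichlet(np.full(n_taxa, config.dirichlet_alpha))
    scale = np.array([config.baseline_scale.get(p, 1.0) for p in phenotypes])
    floor = np.array(
        [config.min_phenotype_baseline.get(p, 0.0) for p in phenotypes]
    )
    ras = np.maximum(raw * scale, floor)
    ras = ras / ras.sum()

    gc = np.clip(
        rng.normal(config.gc_mean, config.gc_sd, size=n_taxa), *config.gc_bounds
    )
    glen = rng.integers(*config.genome_length_range, size=n_taxa)

    taxa = []
    for i in range(n_taxa):
        complement = dict(config.gene_templates[phenotypes[i]])
        if config.background_gene_spacing_bp > 0:
            # The rest of the gene catalogue, pooled as one "none"-family
            # entry whose copy number keeps gene density constant across
            # genomes (otherwise taxon abundance from gene coverage would
            # be biased by how many functional genes a taxon carries).
            n_bg = max(1, round(glen[i] / config.background_gene_spacing_bp))
            complement["none"] = (int(n_bg), config.background_gene_length_nt)
        taxa.append(
            TaxonSpec(
                name=f"taxon_{i:02d}",
                gc_fraction=float(gc[i]),
                genome_length=int(glen[i]),
                baseline_ra=float(ras[i]),
                phenotype=phenotypes[i],
                growth_factor=float(config.growth_factors.get(phenotypes[i], 1.0)),
                gene_complement=complement,
            )
        )
    return taxa


@dataclass
class IncubatedCommunity:
    """Post-incubation state: abundances, per-taxon 13C atom fractions."""

    taxa: tuple[str, ...]
    post_ra: np.ndarray
    atom_fraction: np.ndarray
    total_dna_ng: float


def simulate_incubation(
    community: list[TaxonSpec],
    scheme: LabelingScheme,
    duration_h: float = 96.0,
    total_dna_ng: float = 4000.0,
) -> IncubatedCommunity:
    """Grow the community under a labelling scheme.

    Each taxon's biomass multiplies by ``growth_factor ** (duration_h/96)``
    (the nominal incubation is 96 h); relative abundances are renormalized.
    Pre-existing DNA keeps natural 13C abundance; only replicated DNA
    carries the scheme's incorporated atom fraction, so a taxon's bulk
    atom fraction is the ``1/g`` vs ``(g-1)/g`` mixture of the two, where
    ``g`` is the realized growth of that taxon.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    growth = np.array(
        [t.growth_factor ** (duration_h / 96.0) for t in community]
    )
    baseline = np.array([t.baseline_ra for t in community])
    post = baseline * growth
    if post.sum() <= 0:
        raise ValueError("community died out entirely")
    post = post / post.sum()

    afs = []
    for taxon, g in zip(community, growth):
        try:
            incorporated = scheme.atom_fraction_incorporated[taxon.phenotype]
        except KeyError as exc:
            raise KeyError(
                f"labeling scheme has no atom fraction for phenotype "
                f"{taxon.phenotype!r}"
            ) from exc
        if scheme.is_control or g <= 1.0:
            afs.append(NATURAL_13C_ABUNDANCE)
        else:
            afs.append(NATURAL_13C_ABUNDANCE / g + incorporated * (g - 1.0) / g)
    return IncubatedCommunity(
        taxa=tuple(t.name for t in community),
        post_ra=post,
        atom_fraction=np.array(afs),
        total_dna_ng=total_dna_ng,
    )


@dataclass
class GradientConfig:
    """Physical model of the isopycnic CsCl gradient.

    Unlabelled DNA bands at ``rho_intercept + gc_slope * GC``; full 13C
    labelling adds ``delta_rho_full_label``.  Each taxon's DNA spreads as
    a Gaussian of width ``sigma_density`` over the fraction grid, plus a
    small uniform background (``background_fraction``) standing in for
    diffusion and mixing during fraction recovery.
    """

    n_fractions: int = 12
    density_grid: np.ndarray | None = None
    sigma_density: float = 0.003
    rho_intercept: float = 1.660
    gc_slope: float = 0.098
    delta_rho_full_label: float = 0.036
    natural_abundance: float = NATURAL_13C_ABUNDANCE
    background_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_density <= 0:
            raise ValueError("sigma_density must be positive")
        if self.density_grid is None:
            self.density_grid = np.linspace(1.690, 1.760, self.n_fractions)
        else:
            self.density_grid = np.asarray(self.density_grid, dtype=float)
            self.n_fractions = len(self.density_grid)
        if np.any(self.density_grid < 1.60) or np.any(self.density_grid > 1.80):
            raise ValueError("density grid must lie within [1.60, 1.80] g/mL")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")


def modal_density(
    gc_fraction: float, atom_fraction: float, config: GradientConfig | None = None
) -> float:
    """Buoyant density at which a taxon's DNA bands (g/mL)."""
    config = config or GradientConfig()
    excess = (atom_fraction - config.natural_abundance) / (
        1.0 - config.natural_abundance
    )
    return (
        config.rho_intercept
        + config.gc_slope * gc_fraction
        + config.delta_rho_full_label * excess
    )


def simulate_gradient(
    incubated: IncubatedCommunity,
    community: list[TaxonSpec],
    config: GradientConfig | None = None,
    sample_id: str = "sample",
) -> tuple[pd.DataFrame, list[FractionProfile]]:
    """Distribute each taxon's DNA over the gradient fractions.

    Returns the taxa x fractions DNA-mass matrix (ng; row sums conserve
    each taxon's mass exactly) and the per-fraction profiles with
    refractive indices and column-sum DNA yields.  Emits a warning when
    more than 1% of a taxon's Gaussian mass would band off-grid; the
    weights are renormalized over the grid either way.
    """
    config = config or GradientConfig()
    grid = config.density_grid
    n = len(grid)
    half_step = 0.5 * (grid[1] - grid[0]) if n > 1 else 3 * config.sigma_density
    lo, hi = grid.min() - half_step, grid.max() + half_step

    masses = incubated.post_ra * incubated.total_dna_ng
    gcs = {t.name: t.gc_fraction for t in community}

    rows = np.empty((len(incubated.taxa), n))
    for k, (name, af, mass) in enumerate(
        zip(incubated.taxa, incubated.atom_fraction, masses)
    ):
        rho_k = modal_density(gcs[name], af, config)
        covered = norm.cdf(hi, rho_k, config.sigma_density) - norm.cdf(
            lo, rho_k, config.sigma_density
        )
        if covered < 0.99:
            warnings.warn(
                f"{name}: {100 * (1 - covered):.1f}% of DNA mass bands off-grid "
                f"(modal density {rho_k:.4f} g/mL); renormalizing over the grid",
                stacklevel=2,
            )
        # log-space Gaussian weights: stable even for sigma -> 0, where
        # the nearest fraction takes all of the mass
        log_w = -0.5 * ((grid - rho_k) / config.sigma_density) ** 2
        w = np.exp(log_w - log_w.max())
        w = w / w.sum()
        w = (1.0 - config.background_fraction) * w + config.background_fraction / n
        rows[k] = mass * w

    fraction_ids = [f"F{i + 1:02d}" for i in range(n)]
    matrix = pd.DataFrame(rows, index=list(incubated.taxa), columns=fraction_ids)
    col_sums = matrix.sum(axis=0).to_numpy()
    profiles = [
        FractionProfile(
            sample_id=sample_id,
            fraction_id=fraction_ids[i],
            refractive_index=float(ri_from_density(grid[i])),
            dna_ng=float(col_sums[i]),
        )
        for i in range(n)
    ]
    return matrix, profiles


def simulate_gene_counts(
    pool_mass_per_taxon: dict[str, float] | pd.Series,
    community: list[TaxonSpec],
    depth: int,
    seed: int,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Shotgun-sequence a DNA pool: one multinomial draw over gene targets.

    Read probability for gene g of taxon k is proportional to
    ``mass_k * copies_g * length_g / genome_length_k`` (a genome's reads
    split over its genes in proportion to target length; more genomes of
    a taxon in the pool mean proportionally more reads).  Returns a gene
    hit table with columns sample_id, gene_id, family, taxon, length_nt,
    mapped_reads.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pool = pd.Series(pool_mass_per_taxon, dtype=float)
    if (pool < 0).any():
        raise ValueError("pool masses must be >= 0")
    records = []
    weights = []
    for taxon in community:
        mass = float(pool.get(taxon.name, 0.0))
        for family, (copies, length) in sorted(taxon.gene_complement.items()):
            records.append(
                (sample_id, f"{taxon.name}|{family}", family, taxon.name, length)
            )
            weights.append(mass * copies * length / taxon.genome_length)
    weights = np.array(weights)
    if weights.sum() <= 0:
        raise EmptyPoolError("DNA pool has zero mass; nothing to sequence")
    rng = np.random.default_rng(seed)
    reads = rng.multinomial(depth, weights / weights.sum())
    table = pd.DataFrame(
        records, columns=["sample_id", "gene_id", "family", "taxon", "length_nt"]
    )
    table["mapped_reads"] = reads
    return table


@dataclass
class KineticParams:
    """First-order substrate consumption feeding a volatile product pool.

    Defaults emulate a 100 uM DMSP amendment of coastal seawater in which
    ~77% of the substrate is consumed over 96 h and DMS accumulates and
    is then drawn down.
    """

    s0: float = 100.0  # uM initial substrate
    k_consume: float = 0.0153  # 1/h
    k_dms_consume: float = 0.02  # 1/h
    dms_yield: float = 0.75  # mol DMS per mol substrate consumed
    noise_sd: float = 1.0  # uM measurement noise

    def __post_init__(self) -> None:
        if min(self.s0, self.k_consume, self.k_dms_consume, self.noise_sd) < 0:
            raise ValueError("rates, s0 and noise_sd must be >= 0")
        if not 0.0 <= self.dms_yield <= 1.0:
            raise ValueError("dms_yield must be in [0, 1]")


def timecourse_solution(
    params: KineticParams, times_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free closed-form substrate and DMS concentrations.

    S(t) = s0 exp(-k1 t); the DMS pool obeys
    dDMS/dt = y k1 S - k2 DMS, DMS(0) = 0, giving
    y k1 s0 (exp(-k1 t) - exp(-k2 t)) / (k2 - k1), or the degenerate
    y k1 s0 t exp(-k1 t) when k1 == k2.
    """
    t = np.asarray(times_h, dtype=float)
    k1, k2, y, s0 = params.k_consume, params.k_dms_consume, params.dms_yield, params.s0
    s = s0 * np.exp(-k1 * t)
    if np.isclose(k1, k2):
        dms = y * k1 * s0 * t * np.exp(-k1 * t)
    else:
        dms = y * k1 * s0 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
    return s, dms


def simulate_timecourse(
    params: KineticParams, times_h, seed: int = 0, replicate: str = "rep1"
):
    """Sample a noisy substrate/DMS time course at the given times (h)."""
    from .kinetics import TimeCourse

    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    s, dms = timecourse_solution(params, t)
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        s = np.maximum(s + rng.normal(0, params.noise_sd, t.shape), 0.0)
        dms = np.maximum(dms + rng.normal(0, params.noise_sd, t.shape), 0.0)
    return TimeCourse(time_h=t, dmsp_uM=s, dms_uM=dms, replicate=replicate)


def community_to_frame(community: list[TaxonSpec]) -> pd.DataFrame:
    """Truth table for testing: one row per taxon."""
    return pd.DataFrame(
        {
            "taxon": [t.name for t in community],
            "phenotype": [t.phenotype for t in community],
            "gc_fraction": [t.gc_fraction for t in community],
            "genome_length": [t.genome_length for t in community],
            "baseline_ra": [t.baseline_ra for t in community],
            "growth_factor": [t.growth_factor for t in community],
            "gene_families": [",".join(sorted(t.gene_complement)) for t in community],
        }
    )


def export_gene_fasta(community: list[TaxonSpec], path, seed: int = 0) -> int:
    """Write random-codon nucleotide sequences for every catalogued gene.

    Purely for interoperability with sequence-based tooling: the
    simulator is count-based and the sequences carry no signal beyond
    each taxon's GC content.  Returns the number of records written.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    records = []
    for taxon in community:
        gc = taxon.gc_fraction
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
        for family, (_copies, length) in sorted(taxon.gene_complement.items()):
            seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=f"{taxon.name}|{family}",
                    description=f"synthetic {family} gene, {length} nt",
                )
            )
    with open(path, "w") as handle:
        return seqio_write(records, handle, "fasta")


def write_tables(outdir, community, gene_hits: pd.DataFrame, profiles, timecourse=None):
    """Write the simulator's standard TSV outputs into ``outdir``."""
    from pathlib import Path

    from .fractions import profiles_to_frame

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    community_to_frame(community).to_csv(out / "community.tsv", sep="\t", index=False)
    gene_hits.to_csv(out / "gene_hits.tsv", sep="\t", index=False)
    profiles_to_frame(profiles).to_csv(out / "fractions.tsv", sep="\t", index=False)
    if timecourse is not None:
        timecourse.to_frame().to_csv(out / "timecourse.tsv", sep="\t", index=False)
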