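# Methods

`dmsp_sip` implements the quantitative analysis of a DNA stable-isotope
probing (DNA-SIP) experiment with a *moiety-labelled* substrate —
dimethylsulfoniopropionate (DMSP) whose three propionate carbons are
¹³C-labelled while the dimethylsulfide (DMS) moiety is not — together
with a seeded synthetic-data generator that emulates every stage of such
an experiment so the whole analysis chain is testable without sequencing
data.

## The labelling logic

DMSP degraders fall into distinguishable roles under this labelling
scheme:

- **substrate-carbon users** cleave DMSP (DddD-type lyase plus the
  downstream 3-hydroxypropionate or acrylate route) and assimilate the
  labelled propionate carbons. Their newly replicated DNA is dense:
  they are enriched in the *heavy* gradient fractions of the ¹³C
  incubation but not of the ¹²C control.
- **moiety-gas (DMS) users** grow on the *unlabelled* DMS released by
  the cleavers (methanethiol-oxidase route, *mtoX*). They bloom during
  the incubation but their DNA stays light: enriched overall relative
  to the starting community, yet depleted from the heavy fractions.
- **gene-carrying non-users** hold catabolic genes (*dmdA*, *dddP*)
  without using DMSP for carbon; they neither bloom nor label.

The classifier in `enrichment.classify_assimilators` encodes exactly
this logic as fold-change rules (defaults: heavy/light fold ≥ 4 with a
¹²C-control fold < 2 and, when replicates exist, a significant
whole-incubation enrichment for substrate users; heavy/light fold ≤ 1/4
with whole-incubation enrichment ≥ 4 for DMS users). The source study's
positive calls span 6–137-fold, so the default cut-offs sit below the
smallest reported positive; they are explicit package choices, always
configurable and recorded in output.

## Abundance mathematics

Gene relative abundance is coverage-normalized:
`a_i = (X_i/L_i) / Σ_j (X_j/L_j)` with `X_i` mapped reads and `L_i` gene
length (nt). Taxon abundance is the sum of its genes' `a_i`. The
fraction of cells carrying a gene family is its summed abundance divided
by that of a single-copy marker (*recA* for bacteria, ACTB for
eukaryotes); values above 1 indicate multi-copy families and are flagged,
not clipped. MAG abundance is mean per-nucleotide coverage divided by
the sample's genome equivalents, where genome equivalents use the simple
estimator `total mapped bases / average genome size` (the average genome
size is a configuration input; the synthetic truth is available in
tests). MAGs with ≥ 5% contamination are excluded.

## Gradient model

Unlabelled DNA bands at `ρ = 1.660 + 0.098·GC` g/mL (standard CsCl
values); full ¹³C labelling adds `Δρ = 0.036` g/mL, scaled linearly by
the atom-fraction excess above the natural abundance of 0.011. Each
taxon's DNA spreads over the fraction grid (default 12 fractions,
1.690–1.760 g/mL) as a Gaussian of width `σ = 0.003` g/mL, renormalized
over the grid so mass is conserved exactly (a warning is emitted if
more than 1% of a taxon's mass would band off-grid). A small uniform
background (`background_fraction`, default 1%) is mixed into every
taxon's weights: real gradients show DNA from all taxa in every
fraction (diffusion, wall effects, mixing during recovery), and without
this term the heavy fractions of an unlabelled control would be
populated only by the astronomically small Gaussian tail of the
highest-GC taxon — a degenerate composition no real control shows.
Setting it to 0 restores the pure-Gaussian model.

Refractometry is inverted with the linear CsCl 25 °C relation
`ρ = 10.8601·RI − 13.4974` (overridable for other media). Heavy/light
partitioning uses density thresholds `θ_H = 1.725`, `θ_L = 1.715` g/mL
by default (the band between is excluded from sequencing, as when only
clearly separated gradient regions are analysed); a bimodal-valley rule
is provided and raises a partition-undefined error on unimodal
profiles. The unfractionated community is reconstructed in silico as the
DNA-mass-weighted mixture of the heavy and light abundance tables; the
reconstruction is exact (up to multinomial noise) when the partition is
exhaustive and an approximation when a middle band is excluded.

## Incubation and labelling model

Each taxon's biomass multiplies by `growth_factor^(t/96 h)`. Only
newly replicated DNA carries the incorporated ¹³C fraction; pre-existing
DNA keeps natural abundance, so a taxon's bulk atom fraction after
growing `g`-fold is `(1/g)·0.011 + ((g−1)/g)·f_inc`. The default
incorporated fraction for substrate-carbon users is 0.8 — the three
assimilated propionate carbons are fully labelled, diluted by carbon
drawn from other sources. A ¹²C control scheme pins every taxon at
natural abundance.

## Sequencing model

Each DNA pool (heavy, light, whole gradient, or T0) is sequenced as one
multinomial draw of `depth` reads (default 10⁵) over all (taxon, gene)
targets with probability ∝ `mass · copies · length / genome length`.
Besides its functional genes, every taxon carries a pooled background
catalogue entry (family `none`, one 1-kb gene per 50 kb of genome) so
that catalogued gene density is constant across genomes — without it,
coverage-summed taxon abundance would be biased by how many functional
genes a taxon happens to carry.

## Default study conditions

The generator's defaults emulate a coastal seawater community amended
with a 100 µM DMSP pulse for 96 h at 22 °C: 20 taxa (5% substrate-carbon
users, 10% DMS users, 15% gene-carrying non-users, 70% background);
baseline abundances from a symmetric Dirichlet (α = 1), with degrader
phenotypes down-weighted (×0.3 / ×0.1) to mirror their rarity in
unamended water, and floored at 0.5% so the designed phenotypes are
present at detectable abundance (an absent degrader is not an
informative benchmark); growth factor 16 for both degrader phenotypes
over 96 h, 1 for everyone else; GC content ~ Normal(0.50, 0.015)
clipped to [0.40, 0.60]; genome lengths uniform on 3–6 Mb; 4 µg total
DNA loaded on the gradient; T0 and whole-incubation samples sequenced
in triplicate, heavy/light pools sequenced once (replicates pooled
before sequencing, so their classification relies on folds alone).

The GC spread is deliberately kept small relative to the ~0.027 g/mL
labelling shift. Buoyant density confounds GC with isotope
incorporation; the ¹²C control veto in the classifier is the standard
guard against it and correctly rejects GC-extreme taxa, but in
communities whose GC range rivals the labelling shift this veto costs
sensitivity. The defaults model the favourable regime in which DNA-SIP
is informative; users studying GC-heterogeneous communities should
expect (and can simulate, via `CommunityConfig.gc_sd`) more
conservative behaviour.

## Kinetics

Substrate consumption is first-order, `S(t) = s0·e^(−k₁t)`, feeding a
DMS pool `dDMS/dt = y·k₁·S − k₂·DMS` with the closed-form solution and
its `t·e^(−kt)` degenerate form when `k₁ = k₂`. Defaults
(`s0 = 100 µM`, `k₁ = 0.0153 h⁻¹`, `y = 0.75`, `k₂ = 0.02 h⁻¹`) give
77% substrate consumption over 96 h and an initial removal rate of
~1.1 µM/h when estimated by regression over the first 48 h. Initial
rates are OLS slopes over a window (default 0–48 h; the final 24 h for
late DMS drawdown), reported as positive magnitudes with the direction
recorded; an endpoint-difference estimator is available as an option.
Missing concentrations are dropped pairwise, never imputed. Gas
chromatography calibrations are OLS lines through the standards with a
configured detection limit (0.8 pmol DMS in headspace; 0.15/4 nmol for
DMS/MeSH in incubation monitoring); quantification inverts the line and
flags below-detection amounts. Growth calls on OD₆₀₀ triplicates use the
classical equal-variance two-sample t-test, one-sided (growth is
directional) at α = 0.05; enrichment tests elsewhere are two-sided.
No multiple-testing correction is applied by default; Benjamini–Hochberg
is available behind a flag.

## Gene curation

Metagenome mode retains a hit iff `E ≤ 1e−30` (DMSP-cycling families) or
`E ≤ 1e−5` (DMS-cycling families and markers), identity ≥ 40%, DddD
length ≥ 800 aa, and the query's top hit belongs to the searched family
(the tabular proxy for phylogenetic-clustering confirmation, which is
out of scope — a logged limitation). Isolate mode uses `E ≤ 1e−30`,
identity ≥ 50%, alignment coverage ≥ 70% for every family. All
thresholds are inclusive on the retained side and individually
overridable; all failing conditions are recorded per hit, so curation is
a pure conjunction independent of evaluation order.

## Numerical choices and degenerate inputs

Gaussian gradient weights are computed in log space and shifted by the
row maximum before exponentiation, so the σ → 0 limit concentrates mass
in the nearest fraction instead of underflowing. Fold changes add a
pseudocount (default 10⁻⁵ RA units) to numerator and denominator.
Zero-variance identical groups in t-tests return p = 1 rather than NaN.
Calibrations with fewer than two distinct amounts, zero-slope
inversions, empty DNA pools, empty samples, zero-mass partitions and
out-of-range refractive indices all raise typed errors.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis
assumes: compositional count data, GC- and label-dependent banding,
mass conservation, replicate pooling, and phenotype-linked gene
complements. It does not model read-level errors, amplicon/PCR bias,
chimeras, cross-feeding of labelled catabolites (predatory taxa that
become labelled by eating primary degraders are deliberately left to
fall into the `ambiguous` class), partial genome recovery, taxonomic
misassignment, or ultracentrifugation physics beyond the Gaussian +
background model. Passing recovery tests therefore demonstrate that the
analysis is correct under its own assumptions, not that those
assumptions hold for any particular real data set.

## Problem sizes

The recovery suites use 20 taxa, 12 fractions, 10⁵ reads per sample and
50 seeds (one labelled and one control experiment per seed), which a
single CPU completes in well under a minute; all other checks are
sub-second. These sizes are the package's chosen benchmark conditions
and are configurable through `SIPScenario`.
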