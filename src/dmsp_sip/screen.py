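"""Functional-gene curation and phenotype prediction.

Homology hits against ratified DMSP/DMS-cycling protein references are
filtered by family-specific thresholds before any abundance is reported.
Two rule sets exist: a metagenome mode (stringent E-value for DMSP
cycling families, permissive for DMS families, an identity floor, a
length floor for the unusually long DddD, and the requirement that a
query's top hit falls in the searched family) and an isolate-genome mode
(uniform E-value, identity and alignment-coverage thresholds).  Gene
complements of curated genomes are then mapped to catabolic capabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DMSP_FAMILIES",
    "DMS_FAMILIES",
    "MARKER_FAMILIES",
    "LYSIS_FAMILIES",
    "DMS_OXIDATION_FAMILIES",
    "CurationRule",
    "MissingRuleError",
    "default_rules",
    "apply_curation",
    "predict_phenotype",
]

# DMSP cycling: demethylation, lysis, downstream/ancillary and synthesis.
DMSP_FAMILIES = (
    "dmdA", "dmdB", "dmdC", "dmdD",
    "dddD", "dddL", "dddP", "dddQ", "dddW", "dddY", "dddK", "dddX", "Alma1",
    "dddA", "dddB", "dddC", "dddT",
    "acuI", "acuN", "acuK", "prpE",
    "dsyB", "mmtN", "DSYB", "TpMMT",
)
# DMS cycling and related volatile-sulfur transformations.
DMS_FAMILIES = ("tmm", "DMSOR", "mddA", "ddhA", "dmoA", "mtoX")
# Single-copy phylogenetic markers used for normalization, screened at the
# permissive HMM threshold.
MARKER_FAMILIES = ("recA", "ACTB")

LYSIS_FAMILIES = frozenset(
    {"dddD", "dddL", "dddP", "dddQ", "dddW", "dddY", "dddK", "dddX", "Alma1"}
)
DMS_OXIDATION_FAMILIES = frozenset({"mtoX", "tmm", "ddhA", "dmoA"})


class MissingRuleError(KeyError):
    """A hit's family has no curation rule."""


@dataclass(frozen=True)
class CurationRule:
    """Retention thresholds for one gene family.

    All thresholds are inclusive on the retained side: a hit is kept iff
    ``evalue <= evalue_max``, ``pct_identity >= identity_min``,
    ``query_len_aa >= min_len_aa`` (when set) and
    ``aln_coverage >= coverage_min`` (when set).
    """

    family: str
    evalue_max: float
    identity_min: float
    min_len_aa: int | None = None
    coverage_min: float | None = None
    require_top_hit_same_family: bool = False

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.identity_min < 0:
            raise ValueError("identity_min must be >= 0")


def default_rules(mode: str) -> dict[str, CurationRule]:
    """Family -> rule mapping for the given screening mode.

    ``"metagenome"``: E <= 1e-30 and >= 40% identity for DMSP cycling
    families (DddD additionally >= 800 aa), E <= 1e-5 and >= 40% for DMS
    families, top hit must belong to the searched family; markers at the
    permissive HMM threshold with no identity floor.  ``"isolate"``:
    E <= 1e-30, >= 50% identity, >= 70% alignment coverage for every
    family.
    """
    if mode == "metagenome":
        rules = {}
        for fam in DMSP_FAMILIES:
            rules[fam] = CurationRule(
                family=fam,
                evalue_max=1e-30,
                identity_min=40.0,
                min_len_aa=800 if fam == "dddD" else None,
                require_top_hit_same_family=True,
            )
        for fam in DMS_FAMILIES:
            rules[fam] = CurationRule(
                family=fam,
                evalue_max=1e-5,
                identity_min=40.0,
                require_top_hit_same_family=True,
            )
        for fam in MARKER_FAMILIES:
            rules[fam] = CurationRule(family=fam, evalue_max=1e-5, identity_min=0.0)
        return rules
    if mode == "isolate":
        return {
            fam: CurationRule(
                family=fam, evalue_max=1e-30, identity_min=50.0, coverage_min=70.0
            )
            for fam in DMSP_FAMILIES + DMS_FAMILIES + MARKER_FAMILIES
        }
    raise ValueError(f"unknown screening mode {mode!r}")


def _rejection_reasons(row, rule: CurationRule) -> list[str]:
    reasons = []
    if not row.evalue <= rule.evalue_max:
        reasons.append(f"evalue>{rule.evalue_max:g}")
    if not row.pct_identity >= rule.identity_min:
        reasons.append(f"identity<{rule.identity_min:g}")
    if rule.min_len_aa is not None and not row.query_len_aa >= rule.min_len_aa:
        reasons.append(f"length<{rule.min_len_aa}aa")
    if rule.coverage_min is not None and not row.aln_coverage >= rule.coverage_min:
        reasons.append(f"coverage<{rule.coverage_min:g}")
    if rule.require_top_hit_same_family and not row.top_hit_same_family:
        reasons.append("top_hit_other_family")
    return reasons


def apply_curation(hits: pd.DataFrame, rules: dict[str, CurationRule]) -> pd.DataFrame:
    """Filter a hit table, recording why each rejected hit failed.

    ``hits`` needs columns ``query_id, family, evalue, pct_identity,
    aln_coverage, query_len_aa, top_hit_same_family``.  Returns a copy
    with boolean ``retained`` and string ``rejection_reason`` columns
    (empty for retained hits; all failing conditions listed otherwise,
    so the outcome is independent of evaluation order).
    """
    missing = set(hits["family"]) - set(rules)
    if missing:
        raise MissingRuleError(f"no curation rule for families: {sorted(missing)}")
    reasons = []
    for row in hits.itertuples():
        reasons.append(";".join(_rejection_reasons(row, rules[row.family])))
    out = hits.copy()
    out["rejection_reason"] = reasons
    out["retained"] = [r == "" for r in reasons]
    return out


def predict_phenotype(complement) -> set[str]:
    """Catabolic capabilities implied by a gene complement.

    ``complement`` is an iterable of family names (or a mapping whose
    keys are families).  Capabilities:

    - ``demethylation``: dmdA present;
    - ``lysis``: any known DMSP lyase present;
    - ``carbon_assimilation_ready``: lysis plus a complete downstream
      route — either the 3-hydroxypropionate branch (dddD with dddB or
      dddA, and dddC) or the acrylate branch (prpE and acuI);
    - ``dms_oxidation``: any DMS/MeSH oxidation gene present;
    - ``none`` when nothing applies.

    Unknown families trigger a warning and are ignored.
    """
    families = set(complement)
    known = set(DMSP_FAMILIES) | set(DMS_FAMILIES) | set(MARKER_FAMILIES)
    unknown = families - known
    if unknown:
        warnings.warn(
            f"ignoring unknown gene families: {sorted(unknown)}", stacklevel=2
        )
        families &= known

    capabilities: set[str] = set()
    if "dmdA" in families:
        capabilities.add("demethylation")
    lysis = bool(families & LYSIS_FAMILIES)
    if lysis:
        capabilities.add("lysis")
    hp_route = "dddD" in families and ("dddB" in families or "dddA" in families) and "dddC" in families
    acrylate_route = "prpE" in families and "acuI" in families
    if lysis and (hp_route or acrylate_route):
        capabilities.add("carbon_assimilation_ready")
    if families & DMS_OXIDATION_FAMILIES:
        capabilities.add("dms_oxidation")
    return capabilities or {"none"}
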