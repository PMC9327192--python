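"""Heavy/light enrichment statistics and assimilator classification.

A moiety-labelled SIP design produces samples in up to seven roles: the
natural community (T0), the labelled incubation's heavy and light
gradient pools (13C_H, 13C_L) and its reconstructed or sequenced total
(13C_T), and the same three for the unlabelled control (12C_H, 12C_L,
12C_T).  An entity that assimilated the labelled moiety is enriched in
13C_H relative to 13C_L but shows no such shift in the control; an
entity that bloomed on the *unlabelled* cleavage product is enriched in
the incubation overall yet sits in the light fractions.  This module
turns per-role relative-abundance tables into pseudocount-protected fold
changes, replicate t-tests and a categorical call per entity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROLES",
    "ClassifierThresholds",
    "InsufficientReplicatesError",
    "fold_enrichment",
    "enrichment_test",
    "classify_assimilators",
    "summarize_gene_classes",
]

ROLES = ("T0", "13C_H", "13C_L", "12C_H", "12C_L", "13C_T", "12C_T")

CLASSES = ("substrate_carbon_user", "moiety_gas_user", "unlabeled", "ambiguous")


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates in a group; no t-test possible."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Fold-change and gating thresholds for assimilator calls.

    ``f_heavy``: minimum 13C heavy/light fold for a substrate-carbon
    call (and its reciprocal bounds the light-enrichment side);
    ``f_control``: control heavy/light folds at or above this veto a
    substrate call, and folds within [1/f_control, f_control] across the
    board mean "unlabeled"; ``f_total``: minimum whole-incubation
    enrichment over T0 for a moiety-gas call; ``min_ra``: an entity must
    reach this relative abundance in at least one role to be classified;
    ``pseudocount``: added to numerator and denominator of every fold.
    """

    f_heavy: float = 4.0
    f_control: float = 2.0
    f_total: float = 4.0
    min_ra: float = 0.001
    alpha: float = 0.05
    pseudocount: float = 1e-5
    fdr: bool = False


def fold_enrichment(ra_a: float, ra_b: float, pseudocount: float = 1e-5) -> float:
    """Pseudocount-protected abundance ratio (a + eps) / (b + eps)."""
    if ra_a < 0 or ra_b < 0:
        raise ValueError("relative abundances must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float((ra_a + pseudocount) / (ra_b + pseudocount))


def enrichment_test(replicates_condition, replicates_baseline) -> tuple[float, float]:
    """Two-sided equal-variance two-sample t-test on replicate abundances."""
    a = np.asarray(replicates_condition, dtype=float)
    b = np.asarray(replicates_baseline, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(p):  # identical zero-variance groups
        return 0.0, 1.0
    return float(t), float(p)


def _as_pooled_and_replicates(table) -> tuple[pd.Series, pd.DataFrame | None]:
    """Accept a Series (pooled) or DataFrame (entity x replicate columns)."""
    if isinstance(table, pd.DataFrame):
        return table.mean(axis=1), table
    return table, None


def classify_assimilators(
    ra_tables_by_role: dict[str, pd.Series | pd.DataFrame],
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Classify every entity as substrate-carbon user, moiety-gas user,
    unlabeled, or ambiguous.

    ``ra_tables_by_role`` maps role names (see :data:`ROLES`) to
    relative-abundance tables; 13C_H and 13C_L are mandatory.  Each table
    is either a Series (pooled sample, as when replicates were combined
    before sequencing) or a DataFrame whose columns are replicates — in
    the latter case folds use the replicate mean and the 13C_T-vs-T0
    t-test gates the substrate call; with pooled tables the t-test is
    skipped and classification relies on folds alone.

    Decision rules, with ``f = thresholds``:

    - ``substrate_carbon_user``: fold(13C_H/13C_L) >= f_heavy, the
      control fold (when controls exist) < f_control, and the
      13C_T-vs-T0 test (when replicates exist) significant at alpha;
    - ``moiety_gas_user``: fold(13C_H/13C_L) <= 1/f_heavy and
      fold(13C_T/T0) >= f_total;
    - ``unlabeled``: every available fold within [1/f_control, f_control];
    - ``ambiguous`` otherwise.
    """
    thr = thresholds or ClassifierThresholds()
    for role in ("13C_H", "13C_L"):
        if role not in ra_tables_by_role:
            raise ValueError(f"mandatory role {role!r} missing from design")

    pooled: dict[str, pd.Series] = {}
    reps: dict[str, pd.DataFrame | None] = {}
    for role, table in ra_tables_by_role.items():
        pooled[role], reps[role] = _as_pooled_and_replicates(table)

    entities = pooled["13C_H"].index
    for s in pooled.values():
        entities = entities.union(s.index)

    def ra(role: str, entity) -> float | None:
        if role not in pooled:
            return None
        return float(pooled[role].reindex([entity], fill_value=0.0).iloc[0])

    rows = []
    for entity in entities:
        values = [ra(r, entity) for r in pooled]
        if max(v for v in values if v is not None) < thr.min_ra:
            continue

        f13 = fold_enrichment(ra("13C_H", entity), ra("13C_L", entity), thr.pseudocount)
        f12 = None
        if "12C_H" in pooled and "12C_L" in pooled:
            f12 = fold_enrichment(
                ra("12C_H", entity), ra("12C_L", entity), thr.pseudocount
            )
        f_total = None
        if "13C_T" in pooled and "T0" in pooled:
            f_total = fold_enrichment(
                ra("13C_T", entity), ra("T0", entity), thr.pseudocount
            )

        t_stat = p_val = np.nan
        if reps.get("13C_T") is not None and reps.get("T0") is not None:
            a = reps["13C_T"].reindex([entity], fill_value=0.0).iloc[0].to_numpy()
            b = reps["T0"].reindex([entity], fill_value=0.0).iloc[0].to_numpy()
            if a.size >= 2 and b.size >= 2:
                t_stat, p_val = enrichment_test(a, b)

        rows.append(
            {
                "entity": entity,
                "fold_HL_13C": f13,
                "fold_HL_12C": f12 if f12 is not None else np.nan,
                "fold_T_vs_T0": f_total if f_total is not None else np.nan,
                "t_statistic": t_stat,
                "p_value": p_val,
            }
        )

    records = pd.DataFrame(rows).set_index("entity") if rows else pd.DataFrame(
        columns=["fold_HL_13C", "fold_HL_12C", "fold_T_vs_T0", "t_statistic", "p_value"]
    )
    if records.empty:
        records["class"] = pd.Series(dtype=object)
        return records

    p_for_gate = records["p_value"].copy()
    if thr.fdr:
        mask = p_for_gate.notna()
        if mask.any():
            from statsmodels.stats.multitest import multipletests

            p_for_gate.loc[mask] = multipletests(
                p_for_gate[mask].to_numpy(), method="fdr_bh"
            )[1]

    classes = []
    for entity, rec in records.iterrows():
        f13, f12, f_total = rec["fold_HL_13C"], rec["fold_HL_12C"], rec["fold_T_vs_T0"]
        p = p_for_gate.loc[entity]
        control_ok = np.isnan(f12) or f12 < thr.f_control
        test_ok = np.isnan(p) or p < thr.alpha
        if f13 >= thr.f_heavy and control_ok and test_ok:
            classes.append("substrate_carbon_user")
        elif f13 <= 1.0 / thr.f_heavy and not np.isnan(f_total) and f_total >= thr.f_total:
            classes.append("moiety_gas_user")
        elif all(
            1.0 / thr.f_control <= f <= thr.f_control
            for f in (f13, f12, f_total)
            if not np.isnan(f)
        ):
            classes.append("unlabeled")
        else:
            classes.append("ambiguous")
    records["class"] = classes
    return records


def summarize_gene_classes(
    carrier_fractions: pd.DataFrame,
    pseudocount: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family enrichment report across sample roles.

    ``carrier_fractions`` has columns ``role, family, taxon,
    carrier_fraction`` (marker-normalized gene abundances).  Returns

    - a family-level table with the total carrier fraction per role and
      the heavy/light fold within the labelled incubation, and
    - a composition table giving each taxon's share of a family's
      heavy-fraction total (shares sum to 1 per family and role).

    Families absent from every role are omitted.
    """
    required = {"role", "family", "taxon", "carrier_fraction"}
    if not required <= set(carrier_fractions.columns):
        raise ValueError(f"carrier_fractions needs columns {sorted(required)}")
    totals = (
        carrier_fractions.groupby(["family", "role"])["carrier_fraction"]
        .sum()
        .unstack("role", fill_value=0.0)
    )
    report = totals.copy()
    if "13C_H" in totals.columns and "13C_L" in totals.columns:
        report["fold_HL_13C"] = [
            fold_enrichment(h, l, pseudocount)
            for h, l in zip(totals["13C_H"], totals["13C_L"])
        ]

    shares = carrier_fractions.copy()
    share_totals = shares.groupby(["family", "role"])["carrier_fraction"].transform("sum")
    shares = shares[share_totals > 0].copy()
    shares["share"] = shares["carrier_fraction"] / share_totals[share_totals > 0]
    shares = shares[["role", "family", "taxon", "carrier_fraction", "share"]]
    return report, shares
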