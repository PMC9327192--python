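"""Fold changes, enrichment tests and assimilator classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dmsp_sip.enrichment import (
    ClassifierThresholds,
    InsufficientReplicatesError,
    classify_assimilators,
    enrichment_test,
    fold_enrichment,
    summarize_gene_classes,
)
from tests.test_kinetics import manual_equal_variance_t


class TestFoldEnrichment:
    def test_identity(self):
        assert fold_enrichment(0.3, 0.3) == pytest.approx(1.0)

    def test_arithmetic_with_pseudocount(self):
        assert fold_enrichment(0.10, 0.01, 1e-5) == pytest.approx(
            0.10001 / 0.01001
        )
        assert fold_enrichment(0.10, 0.01, 1e-5) == pytest.approx(9.99, abs=0.01)

    def test_zero_denominator_bounded_by_pseudocount(self):
        fold = fold_enrichment(0.5, 0.0, 1e-5)
        assert np.isfinite(fold)
        assert fold == pytest.approx((0.5 + 1e-5) / 1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(-0.1, 0.2)


class TestEnrichmentTest:
    def test_identical_groups_p_one(self):
        t, p = enrichment_test([0.1, 0.1], [0.1, 0.1])
        assert p == 1.0

    def test_matches_textbook_oracle(self):
        a = [0.01, 0.012, 0.011]
        b = [0.30, 0.31, 0.29]
        t, p = enrichment_test(a, b)
        t_ref, p_ref = manual_equal_variance_t(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)
        assert p < 0.001

    def test_group_swap_negates_t_preserves_p(self):
        a = [0.2, 0.25, 0.22]
        b = [0.1, 0.12, 0.11]
        t1, p1 = enrichment_test(a, b)
        t2, p2 = enrichment_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            enrichment_test([0.1], [0.1, 0.2])


def role_tables(**kwargs):
    return {role: pd.Series(vals) for role, vals in kwargs.items()}


class TestClassifyAssimilators:
    def test_heavy_enriched_with_clean_control_is_substrate_user(self):
        tables = role_tables(
            **{
                "13C_H": {"amph": 0.36, "other": 0.64},
                "13C_L": {"amph": 0.03, "other": 0.97},
                "12C_H": {"amph": 0.05, "other": 0.95},
                "12C_L": {"amph": 0.045, "other": 0.955},
                "T0": {"amph": 0.02, "other": 0.98},
                "13C_T": {"amph": 0.30, "other": 0.70},
            }
        )
        records = classify_assimilators(tables)
        assert records.loc["amph", "class"] == "substrate_carbon_user"

    def test_light_enriched_bloomer_is_moiety_gas_user(self):
        tables = role_tables(
            **{
                "13C_H": {"methylo": 0.01, "other": 0.99},
                "13C_L": {"methylo": 0.20, "other": 0.80},
                "T0": {"methylo": 0.005, "other": 0.995},
                "13C_T": {"methylo": 0.15, "other": 0.85},
            }
        )
        records = classify_assimilators(tables)
        assert records.loc["methylo", "class"] == "moiety_gas_user"

    def test_flat_profile_is_unlabeled(self):
        tables = role_tables(
            **{
                "13C_H": {"x": 0.5, "y": 0.5},
                "13C_L": {"x": 0.5, "y": 0.5},
                "12C_H": {"x": 0.5, "y": 0.5},
                "12C_L": {"x": 0.5, "y": 0.5},
                "T0": {"x": 0.5, "y": 0.5},
                "13C_T": {"x": 0.5, "y": 0.5},
            }
        )
        records = classify_assimilators(tables)
        assert (records["class"] == "unlabeled").all()

    def test_control_enrichment_vetoes_substrate_call(self):
        # heavy-enriched in the labelled run AND in the control: GC artefact
        tables = role_tables(
            **{
                "13C_H": {"hiGC": 0.4, "other": 0.6},
                "13C_L": {"hiGC": 0.05, "other": 0.95},
                "12C_H": {"hiGC": 0.35, "other": 0.65},
                "12C_L": {"hiGC": 0.05, "other": 0.95},
            }
        )
        records = classify_assimilators(tables)
        assert records.loc["hiGC", "class"] == "ambiguous"

    def test_missing_mandatory_role_rejected(self):
        with pytest.raises(ValueError):
            classify_assimilators(role_tables(**{"13C_H": {"x": 1.0}}))

    def test_low_abundance_entities_gated_out(self):
        tables = role_tables(
            **{
                "13C_H": {"rare": 1e-5, "common": 0.99995},
                "13C_L": {"rare": 1e-6, "common": 0.999999},
            }
        )
        records = classify_assimilators(tables)
        assert "rare" not in records.index

    def test_invariant_under_relabeling_and_reordering(self):
        base = {
            "13C_H": {"a": 0.36, "b": 0.04, "c": 0.60},
            "13C_L": {"a": 0.03, "b": 0.47, "c": 0.50},
            "T0": {"a": 0.02, "b": 0.01, "c": 0.97},
            "13C_T": {"a": 0.30, "b": 0.20, "c": 0.50},
        }
        rec1 = classify_assimilators(role_tables(**base))
        renamed = {
            role: {f"z_{k}": v for k, v in vals.items()} for role, vals in base.items()
        }
        shuffled = {
            role: pd.Series(vals).sample(frac=1, random_state=0)
            for role, vals in renamed.items()
        }
        rec2 = classify_assimilators(shuffled)
        for k in base["13C_H"]:
            assert rec1.loc[k, "class"] == rec2.loc[f"z_{k}", "class"]

    def test_matches_brute_force_rule_oracle(self):
        """Exhaustive small grid of fold patterns: the classifier must agree
        with an independent literal evaluation of the decision rules."""
        thr = ClassifierThresholds()
        levels = [0.0005, 0.002, 0.01, 0.05, 0.3]
        rng = np.random.default_rng(5)
        entities = [f"e{i}" for i in range(10)]
        tables = {
            role: pd.Series(rng.choice(levels, len(entities)), index=entities)
            for role in ("13C_H", "13C_L", "12C_H", "12C_L", "T0", "13C_T")
        }
        records = classify_assimilators(tables, thr)

        def oracle(e):
            ras = {r: float(tables[r][e]) for r in tables}
            if max(ras.values()) < thr.min_ra:
                return None
            eps = thr.pseudocount
            f13 = (ras["13C_H"] + eps) / (ras["13C_L"] + eps)
            f12 = (ras["12C_H"] + eps) / (ras["12C_L"] + eps)
            ft = (ras["13C_T"] + eps) / (ras["T0"] + eps)
            if f13 >= thr.f_heavy and f12 < thr.f_control:
                return "substrate_carbon_user"
            if f13 <= 1 / thr.f_heavy and ft >= thr.f_total:
                return "moiety_gas_user"
            if all(1 / thr.f_control <= f <= thr.f_control for f in (f13, f12, ft)):
                return "unlabeled"
            return "ambiguous"

        for e in entities:
            expected = oracle(e)
            if expected is None:
                assert e not in records.index
            else:
                assert records.loc[e, "class"] == expected

    def test_replicate_t_test_gates_substrate_call(self):
        reps = pd.DataFrame(
            {"rep1": [0.30, 0.70], "rep2": [0.31, 0.69], "rep3": [0.29, 0.71]},
            index=["amph", "other"],
        )
        t0 = pd.DataFrame(
            {"rep1": [0.02, 0.98], "rep2": [0.021, 0.979], "rep3": [0.019, 0.981]},
            index=["amph", "other"],
        )
        tables = {
            "13C_H": pd.Series({"amph": 0.36, "other": 0.64}),
            "13C_L": pd.Series({"amph": 0.03, "other": 0.97}),
            "13C_T": reps,
            "T0": t0,
        }
        records = classify_assimilators(tables)
        assert records.loc["amph", "class"] == "substrate_carbon_user"
        assert records.loc["amph", "p_value"] < 0.05
        # same folds but no significant total enrichment: gated out
        tables_null = dict(tables)
        tables_null["13C_T"] = t0 + 0.0001 * np.arange(3)
        records_null = classify_assimilators(tables_null)
        assert records_null.loc["amph", "class"] != "substrate_carbon_user"


class TestSummarizeGeneClasses:
    def _carriers(self):
        return pd.DataFrame(
            [
                ("13C_H", "dddD", "Amphritea", 0.845),
                ("13C_H", "dddD", "Marinomonas", 0.107),
                ("13C_H", "dddD", "Colwellia", 0.048),
                ("13C_L", "dddD", "Amphritea", 0.02),
                ("13C_H", "mtoX", "Methylophaga", 0.0),
                ("13C_L", "mtoX", "Methylophaga", 0.19),
            ],
            columns=["role", "family", "taxon", "carrier_fraction"],
        )

    def test_heavy_shares_mirror_taxon_contributions(self):
        _, shares = summarize_gene_classes(self._carriers())
        heavy_ddd = shares.query("family == 'dddD' and role == '13C_H'")
        by_taxon = dict(zip(heavy_ddd.taxon, heavy_ddd.share))
        assert by_taxon["Amphritea"] == pytest.approx(0.845)
        assert by_taxon["Marinomonas"] == pytest.approx(0.107)
        assert heavy_ddd.share.sum() == pytest.approx(1.0)

    def test_family_only_in_heavy_has_full_heavy_share(self):
        df = pd.DataFrame(
            [("13C_H", "dddW", "Phaeobacter", 0.004)],
            columns=["role", "family", "taxon", "carrier_fraction"],
        )
        report, shares = summarize_gene_classes(df)
        assert shares.share.iloc[0] == pytest.approx(1.0)

    def test_family_fold_heavy_over_light(self):
        report, _ = summarize_gene_classes(self._carriers())
        assert report.loc["dddD", "13C_H"] == pytest.approx(1.0)
        assert report.loc["dddD", "fold_HL_13C"] > 40
        assert report.loc["mtoX", "fold_HL_13C"] < 0.01 / 0.19 + 0.01

    def test_zero_rows_in_a_role_do_not_emit_shares(self):
        _, shares = summarize_gene_classes(self._carriers())
        assert shares.query("family == 'mtoX' and role == '13C_H'").empty


def test_end_to_end_recovery_over_seeds():
    """Designed substrate-carbon users dominate the heavy fraction and are
    recovered; designed DMS users are never called substrate users."""
    from dmsp_sip.pipeline import recovery_rates

    stats = recovery_rates(n_seeds=8, seed0=300)
    assert stats["sensitivity"] >= 0.95
    assert stats["gas_called_substrate"] == 0
    assert stats["heavy_top_rate"] >= 0.95


def test_control_scheme_symmetry():
    """Under a 12C control substrate, heavy/light folds scatter around 1."""
    import warnings

    from dmsp_sip.pipeline import SIPScenario, run_sip_experiment

    log_folds = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(20):
            r = run_sip_experiment(SIPScenario(control_substrate=True), seed=seed)
            log_folds.extend(np.log2(r.records["fold_HL_13C"].to_numpy()))
    log_folds = np.array(log_folds)
    assert abs(log_folds.mean()) < 3 * log_folds.std(ddof=1)
    assert np.all(np.abs(log_folds) < 3.0)  # no taxon even 8-fold shifted
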