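import re

import pytest

from numobat import (
    MissingKeyFeature,
    classify_by_function,
    classify_key,
    evaluate_printed,
    load_default_key,
    load_registry,
)
from numobat.core import Region


class TestEvaluatePrinted:
    def test_intercept_only_when_all_traits_zero(self):
        zeros = {t: 0.0 for t in
                 ("PoOC", "FRS", "SPST", "SL", "SPTI", "EL", "NOH", "SPBA",
                  "ML", "CL", "CWb", "NOL", "SPL", "SPWI", "PEH", "PEW",
                  "PPW", "PPL", "PL")}
        assert evaluate_printed("D3_lichtensteini_laconicus", zeros) == (
            pytest.approx(3.3108, abs=1e-9)
        )

    def test_hand_arithmetic_worked_examples(self):
        v = {"PoOC": 200.0, "FRS": 190.0, "SPST": 185.0}
        # -0.0498*200 - 0.0541*190 + 0.0975*185 + 3.3108
        assert evaluate_printed("D3_lichtensteini_laconicus", v) == (
            pytest.approx(1.1093, abs=1e-9)
        )
        v2 = {"SL": 430.0, "SPST": 180.0, "SPL": 95.0, "SPWI": 190.0}
        # 0.0392*430 - 0.0746*180 + 0.0933*95 - 0.0295*190 - 7.2179
        assert evaluate_printed("D4_crassispinus_crasecundus", v2) == (
            pytest.approx(-0.5314, abs=1e-9)
        )

    def test_unknown_function_and_missing_trait(self):
        with pytest.raises(KeyError, match="known ids"):
            evaluate_printed("D9_nonexistent", {})
        with pytest.raises(KeyError, match="SPST"):
            evaluate_printed("D3_lichtensteini_laconicus", {"PoOC": 1, "FRS": 1})

    def test_frs_sl_quick_ratio(self):
        assert evaluate_printed(
            "FRS_SL_angustifrons", {"FRS": 200.0, "SL": 500.0}
        ) == pytest.approx(0.4)


class TestClassifyByFunction:
    def test_negative_score_assigns_negative_class(self):
        v = {"SL": 430.0, "SPST": 180.0, "SPL": 95.0, "SPWI": 190.0}
        c = classify_by_function("D4_crassispinus_crasecundus", v)
        assert c.taxon == "crassispinus"
        assert c.in_band  # −0.5314 inside [−3.064, −0.075]

    def test_published_laconicus_mean_inside_its_band(self):
        # craft traits scoring exactly +3.085 using a single active term
        score_wanted = 3.085
        spst = (score_wanted - 3.3108 + 0.0498 * 0 + 0.0541 * 0) / 0.0975
        v = {"PoOC": 0.0, "FRS": 0.0, "SPST": spst}
        c = classify_by_function("D3_lichtensteini_laconicus", v)
        assert c.score == pytest.approx(3.085, abs=1e-9)
        assert c.taxon == "laconicus"
        assert c.in_band and c.band_group == "laconicus"

    def test_exact_zero_score_is_a_tie(self):
        ml = 2.811 / 0.0215  # cancels the intercept exactly in doubles
        v = {"SPST": 0.0, "ML": ml}
        assert evaluate_printed("D2_subtilis_helenae", v) == 0.0
        c = classify_by_function("D2_subtilis_helenae", v)
        assert c.tie and c.taxon is None

    def test_score_outside_all_bands_flagged_atypical(self):
        v = {"SPST": 0.0, "ML": 1000.0}  # D2 = 18.7, far above every band
        c = classify_by_function("D2_subtilis_helenae", v)
        assert c.taxon == "subtilis"
        assert not c.in_band and c.atypical

    def test_published_group_means_classify_to_their_taxa(self):
        """For every two-sided function, each published group mean score
        lies on the side of zero that assigns the group's taxon."""
        registry = load_registry()
        for entry in registry:
            if entry["kind"] != "linear":
                continue
            for side in ("negative", "positive"):
                for group in (entry.get(f"pooled_{side}")
                              or [entry[f"{side}_class"]]):
                    for level, stats in entry["groups"].get(group, {}).items():
                        if side == "negative":
                            assert stats["mean"] < 0, (entry["id"], group)
                        else:
                            assert stats["mean"] > 0, (entry["id"], group)

    def test_nest_level_bands_used_when_requested(self):
        v = {"SL": 430.0, "SPST": 180.0, "SPL": 95.0, "SPWI": 190.0}
        c = classify_by_function("D4_crassispinus_crasecundus", v, level="nest")
        assert c.level == "nest" and c.taxon == "crassispinus"


class TestRegistryIntegrity:
    def test_every_coefficient_appears_verbatim_in_its_source(self):
        for entry in load_registry():
            if entry["kind"] != "linear":
                continue
            src = entry["source"]
            for _, coef in entry["terms"]:
                printed = f"{abs(coef):g}".lstrip("0")
                assert printed in src.replace("0.", "."), (entry["id"], coef)
            assert f"{abs(entry['intercept']):g}" in src, entry["id"]

    def test_expected_function_inventory(self):
        registry = load_registry()
        expected = {
            "FRS_SL_angustifrons", "D3_helenae_lucidus",
            "D4_similis_angustifrons_lucidus_subtilis", "D4_subtilis_lucidus",
            "D2_subtilis_helenae", "D3_lichtensteini_laconicus",
            "D4_crassispinus_crasecundus", "D4_ariadnae_helenae",
            "D5_helenae_lucidus_subtilis", "D5_parvulus_helenae",
            "D4_artvinensis_schoedli_tergestinus_sordidulus",
            "D7_sordidulus_tergestinus",
        }
        assert {e["id"] for e in registry} == expected


class TestKeyTraversal:
    def test_antennomere_eleven_is_flavicornis(self):
        res = classify_key({}, antennomere_count=11)
        assert res.taxon == "flavicornis" and res.path == [1]

    def test_low_spine_angle_long_spines_is_laconicus(self):
        res = classify_key({"SPST/CS": 0.40}, antennomere_count=12,
                           spine_angle_deg=22)
        assert res.taxon == "laconicus" and res.path == [1, 2, 3]

    def test_short_spines_is_subtilis(self):
        res = classify_key({"SPST/CS": 0.18}, antennomere_count=12,
                           spine_angle_deg=40)
        assert res.taxon == "subtilis" and res.path == [1, 2, 4]

    def test_missing_feature_names_couplet_and_feature(self):
        with pytest.raises(MissingKeyFeature) as err:
            classify_key({"SPST/CS": 0.30}, antennomere_count=12,
                         spine_angle_deg=40)  # needs PoOC/NOH at couplet 5
        assert err.value.couplet == "5"
        assert err.value.feature == "PoOC/NOH"

    def test_value_in_printed_gap_is_a_tie(self):
        res = classify_key({}, antennomere_count=12, spine_angle_deg=29.0)
        assert res.is_tie and res.tie_at == 2 and res.taxon is None

    def test_exact_threshold_is_a_tie(self):
        res = classify_key({"SPST/CS": 0.384}, antennomere_count=12,
                           spine_angle_deg=22)
        assert res.is_tie and res.tie_at == 3

    def test_region_couplet_requires_region(self):
        features = {"SPST/CS": 0.27, "PoOC/NOH": 2.4, "SPST/CL": 0.25,
                    "CL/CWb": 1.22}
        with pytest.raises(MissingKeyFeature) as err:
            classify_key(features, antennomere_count=12, spine_angle_deg=45)
        assert err.value.couplet == "12"

    def test_single_specimen_mode_attaches_caveat(self):
        res = classify_key({}, antennomere_count=11, single_specimen=True)
        assert any("95%" in c for c in res.caveats)

    # Inputs driving the traversal to each of the 18 leaves, built from
    # the printed thresholds (not from species statistics).
    LEAF_INPUTS = {
        "flavicornis": dict(ratios={}, antennomere_count=11),
        "laconicus": dict(ratios={"SPST/CS": 0.40}, spine_angle_deg=22),
        "lichtensteini": dict(ratios={"SPST/CS": 0.35}, spine_angle_deg=22),
        "subtilis": dict(ratios={"SPST/CS": 0.18}, spine_angle_deg=45),
        "parvulus": dict(
            ratios={"SPST/CS": 0.25, "PoOC/NOH": 2.9}, spine_angle_deg=45
        ),
        "angustifrons": dict(
            ratios={"SPST/CS": 0.29, "PoOC/NOH": 2.9, "FRS/CS": 0.32},
            spine_angle_deg=50,
        ),
        "similis": dict(
            ratios={"SPST/CS": 0.29, "PoOC/NOH": 2.9, "FRS/CS": 0.36,
                    "ML/CS": 1.25},
            spine_angle_deg=50,
        ),
        "helenae": dict(
            ratios={"SPST/CS": 0.29, "PoOC/NOH": 2.9, "FRS/CS": 0.36,
                    "ML/CS": 1.20},
            spine_angle_deg=47,
        ),
        "angulinodis": dict(
            ratios={"SPST/CS": 0.355, "PoOC/NOH": 2.3, "SPST/CL": 0.32,
                    "PEH/CS": 0.41},
            spine_angle_deg=35,
        ),
        "crassispinus": dict(
            ratios={"SPST/CS": 0.33, "PoOC/NOH": 2.4, "SPST/CL": 0.31,
                    "PEH/CS": 0.37},
            spine_angle_deg=37,
        ),
        "sordidulus": dict(
            ratios={"SPST/CS": 0.26, "PoOC/NOH": 2.4, "SPST/CL": 0.23,
                    "CL/CWb": 1.24, "PL/CS": 0.43},
            spine_angle_deg=45, region=Region.EUROPE_MAINLAND,
        ),
        "tergestinus": dict(
            ratios={"SPST/CS": 0.28, "PoOC/NOH": 2.4, "SPST/CL": 0.25,
                    "CL/CWb": 1.21, "PL/CS": 0.40},
            spine_angle_deg=47, region=Region.EUROPE_MAINLAND,
        ),
        "lucidus": dict(
            ratios={"SPST/CS": 0.24, "PoOC/NOH": 2.4, "SPST/CL": 0.21,
                    "CL/CWb": 1.17, "SPBA/CS": 0.26, },
            spine_angle_deg=47,
        ),
        "artvinensis": dict(
            ratios={"SPST/CS": 0.265, "PoOC/NOH": 2.4, "SPST/CL": 0.23,
                    "CL/CWb": 1.24, "SPBA/CWb": 0.31, "NOL/CS": 0.27},
            spine_angle_deg=45, region=Region.ANATOLIA_OR_CRETE,
        ),
        "ariadnae": dict(
            ratios={"SPST/CS": 0.24, "PoOC/NOH": 2.45, "SPST/CL": 0.215,
                    "CL/CWb": 1.22, "SPBA/CWb": 0.31, "NOL/CS": 0.24},
            spine_angle_deg=47, region=Region.ANATOLIA_OR_CRETE,
        ),
        "nylanderi": dict(
            ratios={"SPST/CS": 0.28, "PoOC/NOH": 2.45, "SPST/CL": 0.26,
                    "CL/CWb": 1.14, "SPBA/CS": 0.28},
            spine_angle_deg=38,
        ),
        "schoedli": dict(
            ratios={"SPST/CS": 0.26, "PoOC/NOH": 2.4, "SPST/CL": 0.22,
                    "CL/CWb": 1.17, "SPBA/CS": 0.29, "PoOC/CL": 0.37},
            spine_angle_deg=42,
        ),
        "crasecundus": dict(
            ratios={"SPST/CS": 0.29, "PoOC/NOH": 2.45, "SPST/CL": 0.27,
                    "CL/CWb": 1.15, "SPBA/CS": 0.30, "PoOC/CL": 0.39},
            spine_angle_deg=33, region=Region.EAST_EUROPE_BALKANS_CAUCASUS,
        ),
    }

    @pytest.mark.parametrize("leaf", sorted(LEAF_INPUTS))
    def test_every_leaf_reachable(self, leaf):
        spec = dict(self.LEAF_INPUTS[leaf])
        ratios = spec.pop("ratios")
        spec.setdefault("antennomere_count", 12)
        res = classify_key(ratios, **spec)
        assert res.taxon == leaf, f"expected {leaf}, got {res.taxon} via {res.path}"

    def test_lucidus_reachable_by_second_route(self):
        # couplet 17 (short spines on the mainland-head route)
        res = classify_key(
            {"SPST/CS": 0.24, "PoOC/NOH": 2.4, "SPST/CL": 0.21,
             "CL/CWb": 1.16, "SPBA/CS": 0.26},
            antennomere_count=12, spine_angle_deg=47,
        )
        assert res.taxon == "lucidus"
        assert 17 in res.path


class TestBundledKeyIntegrity:
    def test_thresholds_match_their_stored_quotes(self):
        """Each threshold node's printed quote contains the stored
        threshold value verbatim."""
        key = load_default_key()
        for node_id, node in key.nodes.items():
            if node["type"] != "threshold":
                continue
            quotes = (node.get("quote_low", "") + node.get("quote_high", ""))
            t = node["threshold"]
            forms = {f"{t:g}", f"{t:.3f}", f"{t:.2f}", f"{t:.1f}"}
            assert any(f in quotes for f in forms), (node_id, t)

    def test_leaves_are_valid_taxa(self):
        key = load_default_key()
        for node in key.nodes.values():
            for branch in ("low", "high", "if_match", "else"):
                target = node.get(branch)
                if target and "taxon" in target:
                    assert target["taxon"] in key.taxa

    def test_every_node_has_exactly_two_branches(self):
        key = load_default_key()
        for node_id, node in key.nodes.items():
            if node["type"] in ("categorical", "region"):
                assert "if_match" in node and "else" in node
            else:
                assert "low" in node and "high" in node

    def test_suspect_couplets_flagged_not_corrected(self):
        key = load_default_key()
        assert "suspect" in key.nodes["6"].get("flags", [])
        assert "unreliable_low_range" in key.nodes["11"].get("flags", [])
        assert key.nodes["11"].get("low_range") is None
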