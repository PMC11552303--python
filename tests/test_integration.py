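"""Evidence matrix assembly, candidate filtering and enrichment statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cosegsel.integration import (
    ABSENT,
    PRESENT,
    UP_AVR,
    UP_VIR,
    EvidenceIntegrityError,
    annotation_fractions,
    build_evidence,
    category_enrichment,
    corroboration_rate,
    direction_conflicts,
    is_non_annotated,
    table1_filter,
)


class TestBuildEvidence:
    def test_single_directed_cell(self):
        m = build_evidence({"parent_body": {"g1": "VIR"}})
        assert m.loc["g1", "parent_body"] == UP_VIR
        assert (m.loc["g1"].drop("parent_body") == ABSENT).all()

    def test_three_concordant_cells_from_toy_input(self):
        m = build_evidence({
            "saliva": {"p1": "AVR"},
            "salivary_gland": {"p1": "AVR"},
            "parent_head": {"p1": "AVR"},
        })
        assert (m.loc["p1", ["saliva", "salivary_gland", "parent_head"]] == UP_AVR).all()

    def test_directed_beats_presence(self):
        m = build_evidence({"saliva": {"p1": "VIR"}}, {"saliva": {"p1", "p2"}})
        assert m.loc["p1", "saliva"] == UP_VIR
        assert m.loc["p2", "saliva"] == PRESENT

    def test_contradiction_within_dataset_raises(self):
        with pytest.raises(EvidenceIntegrityError):
            build_evidence({"saliva": [("p1", "VIR"), ("p1", "AVR")]})

    def test_absent_everywhere_excluded(self):
        m = build_evidence({"saliva": {"p1": "VIR"}}, {"salivary_gland": set()})
        assert "p2" not in m.index

    def test_unmapped_ids_reported_not_dropped_silently(self):
        with pytest.warns(UserWarning, match="could not be mapped"):
            m = build_evidence({"saliva": {"x9": "VIR", "x1": "AVR"}},
                               id_map={"x1": "g1"})
        assert list(m.index) == ["g1"]


def _matrix(rows: dict[str, dict[str, str]]) -> pd.DataFrame:
    from cosegsel.integration import DATASETS
    df = pd.DataFrame(ABSENT, index=sorted(rows), columns=list(DATASETS))
    for gid, cells in rows.items():
        for ds, state in cells.items():
            df.loc[gid, ds] = state
    return df


class TestTable1Filter:
    def test_three_datasets_rule(self):
        m = _matrix({"g1": {"saliva": UP_AVR, "salivary_gland": UP_AVR,
                            "parent_head": UP_AVR}})
        out = table1_filter(m).set_index("id")
        assert out.loc["g1", "rule"] == "three_plus"
        assert out.loc["g1", "side"] == "AVR"

    def test_f1_plus_one_rule(self):
        m = _matrix({"g1": {"F1_body": UP_VIR, "saliva": PRESENT}})
        out = table1_filter(m).set_index("id")
        assert out.loc["g1", "rule"] == "f1_plus_one"
        assert out.loc["g1", "side"] == "VIR"

    def test_single_dataset_excluded(self):
        m = _matrix({"g1": {"parent_head": UP_VIR}})
        assert table1_filter(m).empty

    def test_two_datasets_without_f1_excluded(self):
        m = _matrix({"g1": {"parent_head": UP_VIR, "saliva": PRESENT}})
        assert table1_filter(m).empty

    def test_conflicting_directions_labelled(self):
        m = _matrix({"g1": {"parent_body": UP_VIR, "F1_body": UP_AVR,
                            "saliva": PRESENT}})
        out = table1_filter(m).set_index("id")
        assert out.loc["g1", "side"] == "conflict"

    def test_sides_disjoint_and_exclude_conflicts(self):
        m = _matrix({
            "g1": {"saliva": UP_VIR, "salivary_gland": UP_VIR, "parent_body": UP_VIR},
            "g2": {"saliva": UP_AVR, "salivary_gland": UP_AVR, "parent_body": UP_AVR},
            "g3": {"parent_body": UP_VIR, "F1_body": UP_AVR, "saliva": PRESENT},
        })
        out = table1_filter(m)
        vir = set(out[out.side == "VIR"].id)
        avr = set(out[out.side == "AVR"].id)
        assert vir == {"g1"} and avr == {"g2"} and not vir & avr

    def test_monotone_adding_evidence_never_removes(self):
        m = _matrix({"g1": {"F1_body": UP_VIR, "saliva": PRESENT}})
        before = set(table1_filter(m).id)
        m.loc["g1", "salivary_gland"] = PRESENT
        after = set(table1_filter(m).id)
        assert before <= after


class TestConflicts:
    def test_opposed_parent_and_f1(self):
        m = _matrix({
            "g1": {"parent_body": UP_VIR, "F1_body": UP_AVR},
            "g2": {"parent_body": UP_AVR, "F1_body": UP_VIR},
            "g3": {"parent_body": UP_VIR, "F1_body": UP_VIR},
        })
        out = direction_conflicts(m).set_index("id")
        assert out.loc["g1", "pattern"] == "VIRparent/AVRF1"
        assert out.loc["g2", "pattern"] == "AVRparent/VIRF1"
        assert "g3" not in out.index

    def test_presence_never_conflicts(self):
        m = _matrix({"g1": {"parent_body": UP_VIR, "F1_body": PRESENT}})
        assert direction_conflicts(m).empty


class TestCorroboration:
    def test_printed_example(self):
        focal = {f"g{i}" for i in range(24)}
        other = {f"g{i}" for i in range(18)}
        assert corroboration_rate(focal, [other]) == (18, 24, 75)

    def test_none_corroborated(self):
        assert corroboration_rate({"a"}, [set(), set()]) == (0, 1, 0)

    def test_three_of_four(self):
        assert corroboration_rate({"a", "b", "c", "d"},
                                  [{"a"}, {"b", "c"}]) == (3, 4, 75)

    def test_empty_focal_is_error(self):
        with pytest.raises(ValueError):
            corroboration_rate(set(), [{"a"}])


class TestAnnotationFractions:
    @pytest.mark.parametrize("desc,expected", [
        ("hypothetical protein X975_16721", True),
        ("uncharacterized protein LOC100572241", True),
        ("NA", True),
        ("--NA--", True),
        ("ACYPI007553", True),
        ("predicted protein", True),
        ("aminopeptidase N", False),
        ("glutathione S-transferase 1-1-like", False),
        ("ACYPI007553 aminopeptidase", False),
    ])
    def test_non_annotated_rule(self, desc, expected):
        assert is_non_annotated(desc) is expected

    def test_printed_fractions(self):
        ids = [f"p{i}" for i in range(136)]
        ann = pd.DataFrame({
            "description": ["uncharacterized protein X"] * 27
            + ["aminopeptidase N"] * 109,
            "secreted": [True] * 60 + [False] * 76,
        }, index=ids)
        out = annotation_fractions(ids, ann)
        assert out["secreted_pct"] == 44
        assert out["non_annotated_pct"] == 20

    def test_missing_annotation_is_error(self):
        ann = pd.DataFrame({"description": ["x"], "secreted": [False]}, index=["a"])
        with pytest.raises(KeyError):
            annotation_fractions(["a", "b"], ann)


def hypergeom_bruteforce(N: int, K: int, n: int, k: int) -> float:
    """Tail P(X >= k) by explicit enumeration over counts (comb arithmetic)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestEnrichment:
    def test_perfect_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        out = category_enrichment(term, universe, {"T": term})
        assert out["p_value"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_matches_bruteforce_on_all_small_universes(self):
        for N in range(3, 26, 2):
            universe = [f"g{i}" for i in range(N)]
            for K, n in itertools.product((1, N // 3 + 1, N - 1), repeat=2):
                de = set(universe[:n])
                term = set(universe[N - K:])
                out = category_enrichment(de, universe, {"T": term})
                k = len(de & term)
                assert out["p_value"].iloc[0] == pytest.approx(
                    hypergeom_bruteforce(N, K, n, k), rel=1e-9), (N, K, n)

    def test_chance_overlap_is_not_small(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        ps = []
        for _ in range(30):
            de = set(rng.choice(universe, 100, replace=False))
            term = set(rng.choice(universe, 50, replace=False))
            ps.append(category_enrichment(de, universe, {"T": term})["p_value"].iloc[0])
        assert np.mean(ps) > 0.3

    def test_lenient_mode_requires_two_genes(self):
        universe = [f"g{i}" for i in range(100)]
        term = {"g0"}
        out = category_enrichment({"g0"}, universe, {"T": term}, mode="lenient")
        assert out["p_value"].iloc[0] < 0.05 and not out["enriched"].iloc[0]

    def test_strict_mode_uses_fdr(self):
        universe = [f"g{i}" for i in range(40)]
        de = set(universe[:8])
        cats = {"T0": set(universe[:8])}
        cats.update({f"N{i}": {universe[10 + i]} for i in range(20)})
        out = category_enrichment(de, universe, cats, mode="strict").set_index("term")
        assert bool(out.loc["T0", "enriched"])

    def test_wallenius_equal_weights_matches_hypergeom(self):
        universe = [f"g{i}" for i in range(30)]
        de = set(universe[:10])
        term = set(universe[5:15])
        plain = category_enrichment(de, universe, {"T": term})
        w = {g: 1.0 for g in universe}
        biased = category_enrichment(de, universe, {"T": term}, bias_weights=w)
        assert biased["p_value"].iloc[0] == pytest.approx(
            plain["p_value"].iloc[0], rel=1e-6)

    def test_empty_overlap_term_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = category_enrichment({"g0"}, ["g0", "g1"], {"T": {"zz"}})
        assert out.empty

    def test_de_set_must_be_subset(self):
        with pytest.raises(ValueError):
            category_enrichment({"zz"}, ["g0"], {"T": {"g0"}})
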