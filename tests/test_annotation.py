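import pytest

from messar.annotation import (
    aggregate_exhaustive,
    aggregate_fast,
    aggregate_naive,
    annotate_motif,
    match_rules,
)
from messar.chemistry import Substructure, canonical_smiles, contains_substructure
from messar.feature_extraction import (
    MASS,
    MDIFF,
    FeatureSet,
    SpectralFeature,
    extract_query_features,
)
from messar.rule_mining import Rule

BENZENE = canonical_smiles("c1ccccc1")
TOLUENE = canonical_smiles("Cc1ccccc1")


def make_rule(rid, body_values, head, tp=8, supp_y=10, supp_x=10, ftype=MDIFF):
    return Rule(
        rule_id=rid,
        body=frozenset(SpectralFeature(ftype, v) for v in body_values),
        head=Substructure.from_smiles(head),
        supp_x=supp_x,
        supp_y=supp_y,
        tp=tp,
        origin="target",
    )


def query(values, ftype=MDIFF):
    return FeatureSet("q", frozenset(SpectralFeature(ftype, v) for v in values))


class TestMatchRules:
    def test_exact_single_feature_match(self):
        db = [make_rule(1, [18.0106], BENZENE)]
        assert len(match_rules(query([18.0106]), db)) == 1

    def test_conjunctive_body_requires_all_features(self):
        db = [make_rule(1, [18.0106, 28.0313], BENZENE)]
        assert match_rules(query([18.0106]), db) == []
        assert len(match_rules(query([18.0106, 28.0313]), db)) == 1

    def test_30_ppm_away_fails_at_20_ppm(self):
        value = 172.0757
        off = round(value * (1 + 30e-6), 4)
        db = [make_rule(1, [value], BENZENE)]
        assert match_rules(query([off]), db, ppm=20) == []
        assert len(match_rules(query([off]), db, ppm=40)) == 1

    def test_ranked_by_recall(self):
        db = [
            make_rule(1, [10.0], BENZENE, tp=3, supp_y=10),
            make_rule(2, [20.0], TOLUENE, tp=9, supp_y=10),
        ]
        matches = match_rules(query([10.0, 20.0]), db)
        assert [m.rule.rule_id for m in matches] == [2, 1]


class TestAggregateNaive:
    def test_identical_heads_pooled(self):
        db = [
            make_rule(1, [10.0], BENZENE, tp=6, supp_y=10),
            make_rule(2, [20.0], BENZENE, tp=3, supp_y=10),
        ]
        recs = aggregate_naive(match_rules(query([10.0, 20.0]), db))
        assert len(recs) == 1
        assert recs[0].score == pytest.approx(0.9)
        assert recs[0].contributing_rule_ids == frozenset({1, 2})

    def test_distinct_heads_stay_separate(self):
        db = [
            make_rule(1, [10.0], BENZENE),
            make_rule(2, [20.0], "CCCCCO"),
        ]
        assert len(aggregate_naive(match_rules(query([10.0, 20.0]), db))) == 2

    def test_empty_matches(self):
        assert aggregate_naive([]) == []


class TestAggregateExhaustive:
    def test_identical_heads_mcs_is_the_head(self):
        db = [
            make_rule(1, [10.0], BENZENE, tp=4, supp_y=10),
            make_rule(2, [20.0], BENZENE, tp=5, supp_y=10),
        ]
        recs = aggregate_exhaustive(match_rules(query([10.0, 20.0]), db))
        assert len(recs) == 1
        assert recs[0].substructure.smiles == BENZENE
        assert recs[0].score == pytest.approx(0.9)

    def test_dissimilar_heads_pass_through(self):
        db = [
            make_rule(1, [10.0], BENZENE),
            make_rule(2, [20.0], "CCCCCCCCCO"),
        ]
        recs = aggregate_exhaustive(match_rules(query([10.0, 20.0]), db))
        assert {r.substructure.smiles for r in recs} == {BENZENE, "CCCCCCCCCO"}

    def test_analogous_pair_reduces_to_mcs_with_passthrough(self):
        # toluene and ethylbenzene heads are analogous (Tanimoto > 0.5),
        # their MCS is toluene; the aliphatic head passes through alone
        db = [
            make_rule(1, [10.0], TOLUENE, tp=4, supp_y=10),
            make_rule(2, [20.0], "CCc1ccccc1", tp=5, supp_y=10),
            make_rule(3, [30.0], "CCCCCCCCCO", tp=6, supp_y=10),
        ]
        recs = aggregate_exhaustive(match_rules(query([10.0, 20.0, 30.0]), db))
        by_smiles = {r.substructure.smiles: r for r in recs}
        assert by_smiles[TOLUENE].score == pytest.approx(0.9)  # both rules
        assert by_smiles[TOLUENE].contributing_rule_ids == frozenset({1, 2})
        assert by_smiles["CCCCCCCCCO"].score == pytest.approx(0.6)

    def test_small_recommendations_dropped(self):
        db = [make_rule(1, [10.0], "CCl")]
        assert aggregate_exhaustive(match_rules(query([10.0]), db)) == []
        kept = aggregate_exhaustive(match_rules(query([10.0]), db), small_filter=2)
        assert len(kept) == 1

    def test_scores_equal_sum_of_contributing_recalls(self):
        db = [
            make_rule(i, [10.0 * i], head, tp=3 + i, supp_y=12)
            for i, head in enumerate(
                [BENZENE, TOLUENE, "CCc1ccccc1", "CCCCCCCCCO", "OCCCCCCCCO"], start=1
            )
        ]
        matches = match_rules(query([10.0 * i for i in range(1, 6)]), db)
        by_id = {r.rule_id: r for r in (m.rule for m in matches)}
        for rec in aggregate_exhaustive(matches):
            expected = sum(by_id[i].recall for i in rec.contributing_rule_ids)
            assert rec.score == pytest.approx(expected)

    def test_ranks_are_contiguous_and_scores_sorted(self):
        db = [
            make_rule(1, [10.0], BENZENE, tp=9, supp_y=10),
            make_rule(2, [20.0], "CCCCCCCCCO", tp=5, supp_y=10),
        ]
        recs = aggregate_exhaustive(match_rules(query([10.0, 20.0]), db))
        assert [r.rank for r in recs] == [1, 2]
        scores = [r.score for r in recs]
        assert scores == sorted(scores, reverse=True)


class TestAggregateFast:
    def test_equals_exhaustive_for_up_to_20_matches(self):
        db = [
            make_rule(i, [float(10 + i)], head, tp=3 + (i % 5), supp_y=12)
            for i, head in enumerate(
                [BENZENE, TOLUENE, "CCc1ccccc1", "CCCCCCCCCO", "Oc1ccccc1"] * 4, start=1
            )
        ]
        q = query([float(10 + i) for i in range(1, 21)])
        matches = match_rules(q, db)
        assert len(matches) == 20
        fast = aggregate_fast(matches)
        full = aggregate_exhaustive(matches)
        assert [(r.substructure.smiles, r.score) for r in fast] == [
            (r.substructure.smiles, r.score) for r in full
        ]

    def test_truncates_to_top_20_by_recall(self):
        db = [
            make_rule(i, [float(10 + i)], BENZENE, tp=i % 10 + 1, supp_y=12)
            for i in range(1, 26)
        ]
        matches = match_rules(query([float(10 + i) for i in range(1, 26)]), db)
        fast = aggregate_fast(matches)
        contributing = set().union(*(r.contributing_rule_ids for r in fast))
        top20 = {
            m.rule.rule_id
            for m in sorted(matches, key=lambda m: (-m.rule.recall, m.rule.rule_id))[:20]
        }
        assert contributing <= top20

    def test_empty(self):
        assert aggregate_fast([]) == []


class TestAnnotateMotif:
    def test_single_matching_rule_returns_its_head(self):
        db = [make_rule(1, [18.0106], BENZENE)]
        result = annotate_motif([(MDIFF, 18.0106, 0.9)], db)
        assert result.status == "annotated"
        assert result.substructure.smiles == BENZENE

    def test_recall_breaks_ties_within_shared_body(self):
        db = [
            make_rule(1, [18.0106], BENZENE, tp=6, supp_y=10),
            make_rule(2, [18.0106], "CCCCCCCCCO", tp=4, supp_y=10),
        ]
        result = annotate_motif([(MDIFF, 18.0106, 0.9)], db)
        assert result.substructure.smiles == BENZENE

    def test_exact_tie_reports_mcs_of_tied_heads(self):
        db = [
            make_rule(1, [18.0106], TOLUENE, tp=5, supp_y=10),
            make_rule(2, [18.0106], "CCc1ccccc1", tp=5, supp_y=10),
        ]
        result = annotate_motif([(MDIFF, 18.0106, 0.9)], db)
        assert result.substructure.smiles == TOLUENE  # MCS(toluene, ethylbenzene)

    def test_only_top_k_features_considered(self):
        db = [make_rule(1, [99.0], BENZENE)]
        feats = [(MDIFF, float(i), 1.0 - i * 0.01) for i in range(1, 51)]
        feats.append((MDIFF, 99.0, 0.01))  # rank 51: ignored
        result = annotate_motif(feats, db, top_k=50)
        assert result.status == "no annotation"

    def test_no_matches(self):
        db = [make_rule(1, [500.0], BENZENE)]
        result = annotate_motif([(MASS, 10.0, 0.5)], db)
        assert result.status == "no annotation"
        assert result.substructure is None


class TestEndToEndPlanted:
    def test_query_ranks_planted_substructure_first(self):
        from messar import build_transactions, generate_library, generate_query, mine_rules
        from messar.feature_extraction import extract_target_features
        from messar.synthetic_fixtures import MULTI_FAMILY_PATTERNS, multi_family_spec

        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            spec = multi_family_spec(seed=seed, emit_prob=0.9)
            lib = generate_library(spec)
            feats = [extract_target_features(r) for r in lib.records]
            txns = build_transactions(lib, feats, MULTI_FAMILY_PATTERNS, max_cuts=0)
            rules = mine_rules(txns)

            # pick a phenol-family compound and annotate its query spectrum
            idx = next(
                i
                for i, r in enumerate(lib.records)
                if contains_substructure(r.structure, "Oc1ccccc1")
            )
            q = generate_query(spec, idx)
            matches = match_rules(extract_query_features(q), rules)
            recs = aggregate_exhaustive(matches)
            if recs and contains_substructure(
                recs[0].substructure.smiles, "Oc1ccccc1"
            ):
                hits += 1
        assert hits / n_rep >= 0.9
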