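"""Span matching, metric arithmetic, agreement and fold splitting."""

import itertools
import random

import pytest

import metevent as me
from metevent.evaluation import ALL, ANY, EXACT, SLOPPY, EvalCounts, MatchConfig


def ent(eid, etype, start, end):
    return me.Entity(eid, etype, start, end, "x" * (end - start))


class TestMatchEntities:
    def test_overlap_counts_under_sloppy_not_exact(self):
        pred = [ent("T1", me.GP, 0, 10)]
        gold = [ent("G1", me.GP, 5, 25)]
        sloppy = me.match_entities(pred, gold, MatchConfig(entity_mode=SLOPPY))
        exact = me.match_entities(pred, gold, MatchConfig(entity_mode=EXACT))
        assert sloppy[me.GP].tp == 1
        assert exact[me.GP].tp == 0 and exact[me.GP].fp == 1 and exact[me.GP].fn == 1

    def test_type_mismatch_never_matches(self):
        pred = [ent("T1", me.METABOLITE, 0, 4)]
        gold = [ent("G1", me.GP, 0, 4)]
        counts = me.match_entities(pred, gold)
        assert counts[me.METABOLITE].fp == 1 and counts[me.GP].fn == 1

    def test_one_to_one_constraint(self):
        pred = [ent("T1", me.GP, 0, 5), ent("T2", me.GP, 3, 8)]
        gold = [ent("G1", me.GP, 2, 6)]
        c = me.match_entities(pred, gold)[me.GP]
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_exhaustive_brute_force_equivalence(self):
        """Matched counts equal the brute-force maximum one-to-one matching
        for every pred/gold subset of a small span universe (<= 8 spans)."""
        universe = [(0, 3), (2, 5), (4, 7), (6, 9), (10, 12), (11, 14), (20, 22), (1, 8)]

        def brute(pred, gold):
            best = 0
            for k in range(min(len(pred), len(gold)), 0, -1):
                for p_sub in itertools.permutations(range(len(pred)), k):
                    for g_sub in itertools.combinations(range(len(gold)), k):
                        if all(
                            pred[i][0] < gold[j][1] and gold[j][0] < pred[i][1]
                            for i, j in zip(p_sub, g_sub)
                        ):
                            return k
            return best

        rng = random.Random(1)
        for _ in range(300):
            pred_spans = rng.sample(universe, rng.randint(0, 4))
            gold_spans = rng.sample(universe, rng.randint(0, 4))
            pred = [ent(f"T{i}", me.GP, *s) for i, s in enumerate(pred_spans)]
            gold = [ent(f"G{i}", me.GP, *s) for i, s in enumerate(gold_spans)]
            counts = me.match_entities(pred, gold)
            tp = counts[me.GP].tp if counts else 0
            assert tp == brute(pred_spans, gold_spans)

    def test_swap_symmetry(self):
        pred = [ent("T1", me.GP, 0, 5), ent("T2", me.GP, 10, 15)]
        gold = [ent("G1", me.GP, 3, 8)]
        a = me.match_entities(pred, gold)[me.GP]
        b = me.match_entities(gold, pred)[me.GP]
        pa, ra, fa = me.prf(a)
        pb, rb, fb = me.prf(b)
        assert (pa, ra) == (rb, pb) and fa == fb


def _event(eid, evtype, tstart, tend, themes, causes=()):
    return me.MetabolicEvent(eid, evtype, tstart, tend, "t" * (tend - tstart), themes, causes)


class TestMatchEvents:
    def _setting(self):
        p_ents = [ent("T1", me.METABOLITE, 0, 5), ent("T2", me.GP, 20, 25)]
        g_ents = [ent("U1", me.METABOLITE, 1, 6), ent("U2", me.GP, 40, 45)]
        pred = [_event("E1", me.PRODUCTION, 8, 14, ("T1",), ("T2",))]
        gold = [_event("F1", me.PRODUCTION, 10, 16, ("U1",), ("U2",))]
        return pred, gold, p_ents, g_ents

    def test_identical_event_matches_in_both_modes(self):
        p_ents = [ent("T1", me.METABOLITE, 0, 5)]
        pred = [_event("E1", me.PRODUCTION, 8, 14, ("T1",))]
        for mode in (ANY, ALL):
            c = me.match_events(pred, pred, p_ents, p_ents,
                                MatchConfig(event_arg_mode=mode))
            assert c[me.PRODUCTION].tp == 1

    def test_partial_arguments_any_vs_all(self):
        """One of two arguments agreeing matches under 'any' but not 'all'."""
        pred, gold, p_ents, g_ents = self._setting()
        any_c = me.match_events(pred, gold, p_ents, g_ents, MatchConfig(event_arg_mode=ANY))
        all_c = me.match_events(pred, gold, p_ents, g_ents, MatchConfig(event_arg_mode=ALL))
        assert any_c[me.PRODUCTION].tp == 1
        assert all_c[me.PRODUCTION].tp == 0

    def test_event_type_must_match(self):
        pred, gold, p_ents, g_ents = self._setting()
        gold = [_event("F1", me.CONSUMPTION, 10, 16, ("U1",), ("U2",))]
        c = me.match_events(pred, gold, p_ents, g_ents)
        assert c[me.PRODUCTION].fp == 1 and c[me.CONSUMPTION].fn == 1

    def test_disjoint_triggers_do_not_match(self):
        pred, gold, p_ents, g_ents = self._setting()
        gold = [_event("F1", me.PRODUCTION, 30, 36, ("U1",), ("U2",))]
        assert me.match_events(pred, gold, p_ents, g_ents)[me.PRODUCTION].tp == 0

    def test_nested_event_arguments_compared_recursively(self):
        p_ents = [ent("T1", me.METABOLITE, 0, 5), ent("T2", me.GP, 30, 34)]
        g_ents = [ent("U1", me.METABOLITE, 2, 7), ent("U2", me.GP, 31, 35)]
        pred = [
            _event("E1", me.PRODUCTION, 8, 14, ("T1",)),
            _event("E2", me.POSITIVE_REGULATION, 20, 26, ("E1",), ("T2",)),
        ]
        gold = [
            _event("F1", me.PRODUCTION, 9, 15, ("U1",)),
            _event("F2", me.POSITIVE_REGULATION, 21, 27, ("F1",), ("U2",)),
        ]
        c = me.match_events(pred, gold, p_ents, g_ents, MatchConfig(event_arg_mode=ALL))
        assert c[me.POSITIVE_REGULATION].tp == 1

    def test_all_never_beats_any(self):
        pred, gold, p_ents, g_ents = self._setting()
        for g in (gold, [_event("F1", me.PRODUCTION, 10, 16, ("U1",))]):
            tp_any = me.match_events(pred, g, p_ents, g_ents,
                                     MatchConfig(event_arg_mode=ANY))[me.PRODUCTION].tp
            tp_all = me.match_events(pred, g, p_ents, g_ents,
                                     MatchConfig(event_arg_mode=ALL))[me.PRODUCTION].tp
            assert tp_all <= tp_any


class TestMetricArithmetic:
    def test_prf_basic(self):
        p, r, f = me.prf(EvalCounts(tp=1, fp=1, fn=3))
        assert (p, r) == (0.5, 0.25)
        assert f == pytest.approx(2 * 0.5 * 0.25 / 0.75)

    def test_all_zero_convention(self):
        assert me.prf(EvalCounts()) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            me.prf(EvalCounts(tp=-1))

    def test_micro_single_category_is_identity(self):
        c = EvalCounts(tp=3, fp=1, fn=2)
        assert me.micro_average([c]) == me.prf(c)

    def test_micro_hand_summed(self):
        cs = [EvalCounts(tp=1, fp=0, fn=1), EvalCounts(tp=0, fp=1, fn=0)]
        assert me.micro_average(cs) == (0.5, 0.5, 0.5)

    def test_micro_empty_rejected(self):
        with pytest.raises(ValueError):
            me.micro_average([])

    def test_micro_equals_prf_of_sums(self):
        rng = random.Random(3)
        cs = [EvalCounts(rng.randint(0, 9), rng.randint(0, 9), rng.randint(0, 9))
              for _ in range(6)]
        total = EvalCounts(sum(c.tp for c in cs), sum(c.fp for c in cs),
                           sum(c.fn for c in cs))
        assert me.micro_average(cs) == me.prf(total)


class TestInteractionEvaluation:
    def test_identical_sets_are_perfect(self):
        pairs = [("E", "m1"), ("E", "m2")]
        c = me.evaluate_interactions(pairs, pairs)
        assert me.prf(c) == (1.0, 1.0, 1.0)

    def test_direction_insensitive_by_default(self):
        pred = [("E", "m1", "produces")]
        gold = [("E", "m1", "consumes")]
        assert me.evaluate_interactions(pred, gold).tp == 1
        assert me.evaluate_interactions(pred, gold, direction_sensitive=True).tp == 0

    def test_synonym_map_applies_to_both_sides(self):
        syn = {"old name": "new name"}
        c = me.evaluate_interactions([("old name", "m")], [("new name", "m")], syn)
        assert c.tp == 1


class TestCohensKappa:
    def test_identical_annotations(self):
        labels = ["a", "b", "a", "c"]
        assert me.cohens_kappa(labels, labels).kappa == 1.0

    def test_hand_computed_confusion_table(self):
        """10 items, confusion [[4,1],[1,4]]: p_o=0.8, p_e=0.5, kappa=0.6."""
        a = ["x"] * 5 + ["y"] * 5
        b = ["x"] * 4 + ["y"] + ["x"] + ["y"] * 4
        res = me.cohens_kappa(a, b)
        assert res.p_observed == pytest.approx(0.8)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_random_labelling_gives_near_zero_kappa(self):
        rng = random.Random(11)
        n = 10_000
        a = [rng.choice(["x", "y", "z"]) for _ in range(n)]
        b = list(a)
        rng.shuffle(b)  # same marginals, independent of a
        assert abs(me.cohens_kappa(a, b).kappa) < 0.05

    def test_degenerate_single_category(self):
        # chance agreement is 1 but so is observed agreement
        assert me.cohens_kappa(["x", "x"], ["x", "x"]).kappa == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            me.cohens_kappa([], [])


class TestAgreementLabels:
    def test_overlapping_annotations_unify(self):
        text = "leucine pool"
        a = me.AnnotatedDocument("d", text, [ent("T1", me.METABOLITE, 0, 7)], [])
        b = me.AnnotatedDocument("d", text, [ent("T1", me.METABOLITE, 2, 9)], [])
        la, lb = me.agreement_labels([a], [b], "entities")
        assert la == [me.METABOLITE] and lb == [me.METABOLITE]

    def test_unmatched_items_pair_with_none(self):
        text = "leucine pool"
        a = me.AnnotatedDocument("d", text, [ent("T1", me.METABOLITE, 0, 7)], [])
        b = me.AnnotatedDocument("d", text, [ent("T1", me.GP, 9, 12)], [])
        la, lb = me.agreement_labels([a], [b], "entities")
        assert sorted(zip(la, lb)) == [(me.METABOLITE, "none"), ("none", me.GP)]


class TestConsensusFscore:
    def test_identical_annotator_scores_one(self, glmm_doc):
        scores = me.consensus_fscore([glmm_doc], [glmm_doc])
        assert all(f == 1.0 for _, _, f in scores.values())

    def test_missing_half_gives_half_recall_full_precision(self):
        text = "a b c d"
        gold_ents = [ent("T1", me.GP, 0, 1), ent("T2", me.GP, 4, 5)]
        gold = me.AnnotatedDocument("d", text, gold_ents, [])
        partial = me.AnnotatedDocument("d", text, gold_ents[:1], [])
        p, r, f = me.consensus_fscore([partial], [gold])[me.GP]
        assert (p, r) == (1.0, 0.5)

    def test_doc_id_mismatch_rejected(self, glmm_doc):
        other = me.AnnotatedDocument("other", "x", [], [])
        with pytest.raises(ValueError):
            me.consensus_fscore([glmm_doc], [other])


class TestKfold:
    def test_fold_sizes_differ_by_at_most_one(self):
        folds = me.kfold_split([f"d{i}" for i in range(271)], 5, seed=1)
        assert sorted(len(f) for f in folds) == [54, 54, 54, 54, 55]

    def test_deterministic_and_partitioning(self):
        ids = [f"d{i}" for i in range(23)]
        a = me.kfold_split(ids, 5, seed=9)
        b = me.kfold_split(ids, 5, seed=9)
        assert a == b
        flat = [d for fold in a for d in fold]
        assert sorted(flat) == sorted(ids) and len(set(flat)) == len(ids)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            me.kfold_split(["a", "b"], 5)


def test_exact_mode_never_beats_sloppy():
    rng = random.Random(5)
    for _ in range(50):
        pred = [ent(f"T{i}", me.GP, s, s + rng.randint(1, 4))
                for i, s in enumerate(rng.sample(range(0, 30), rng.randint(0, 5)))]
        gold = [ent(f"G{i}", me.GP, s, s + rng.randint(1, 4))
                for i, s in enumerate(rng.sample(range(0, 30), rng.randint(0, 5)))]
        tp_sloppy = sum(c.tp for c in me.match_entities(
            pred, gold, MatchConfig(entity_mode=SLOPPY)).values())
        tp_exact = sum(c.tp for c in me.match_entities(
            pred, gold, MatchConfig(entity_mode=EXACT)).values())
        assert tp_exact <= tp_sloppy
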