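"""Relation classes, sensitivity/error curves, alignment accuracy, tuning."""

import io

import numpy as np
import pytest
from dataclasses import replace

from alignhush import (
    HomologyLabel,
    ReferenceAlignment,
    RelationClass,
    ScoringParams,
    alignment_accuracy,
    classify_relation,
    compose_alignments,
    roc_auc,
    sensitivity_at_error,
    sensitivity_error_curve,
    tune_parameters,
)
from alignhush.benchmark import (
    count_true_relations,
    dedupe_hits,
    read_labels_tsv,
    reference_from_aligned_pair,
)
from alignhush.errors import AlignHushError, BenchmarkError, ContractViolation

TRUE = RelationClass.TRUE_POSITIVE_ELIGIBLE
FALSE = RelationClass.FALSE_POSITIVE_ELIGIBLE
IGN = RelationClass.IGNORED


def lab(code):
    return HomologyLabel.from_ccs(code)


class TestRelations:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("1.1.1.1", "1.1.1.2", TRUE),    # same superfamily, diff family
            ("1.1.1.1", "2.1.1.1", FALSE),   # different class
            ("1.1.1.1", "1.1.2.1", IGN),     # same fold, diff superfamily
            ("1.1.1.1", "1.2.1.1", IGN),     # same class, diff fold
            ("1.1.1.1", "1.1.1.1", IGN),     # same family: not scored
        ],
    )
    def test_classification_rules(self, a, b, expected):
        assert classify_relation(lab(a), lab(b)) is expected
        assert classify_relation(lab(b), lab(a)) is expected

    def test_labels_tsv_roundtrip(self):
        text = "# comment\np1\t1.2.3.4\np2\t2.1.1.1\n"
        labels = read_labels_tsv(io.StringIO(text))
        assert labels["p1"].scop_class == "1"
        assert labels["p1"].fold == "1.2"
        assert labels["p1"].superfamily == "1.2.3"
        assert labels["p1"].family == "1.2.3.4"

    def test_count_true_relations_unordered(self):
        labels = {f"p{i}": lab(f"1.1.1.{i}") for i in range(4)}
        # 4 families in one superfamily -> C(4,2) unordered true pairs
        assert count_true_relations(labels) == 6


class TestCurve:
    def test_nine_true_one_false_at_twenty_positives(self):
        hits = [(10.0 - k, TRUE) for k in range(9)] + [(0.5, FALSE)]
        curve = sensitivity_error_curve(hits, n_true_relations=20)
        assert curve[-1] == (pytest.approx(0.10), pytest.approx(0.45))

    def test_all_ignored_gives_empty_curve(self):
        assert sensitivity_error_curve([(5.0, IGN), (4.0, IGN)], 10) == []

    def test_ignored_hits_do_not_perturb_curve(self):
        base = [(9.0, TRUE), (8.0, FALSE), (7.0, TRUE)]
        noisy = [(9.5, IGN)] + base + [(7.5, IGN), (6.0, IGN)]
        assert sensitivity_error_curve(base, 5) == sensitivity_error_curve(noisy, 5)

    def test_error_rate_rises_at_each_false_hit(self):
        hits = [(9.0, TRUE), (8.0, FALSE), (7.0, TRUE), (6.0, FALSE)]
        curve = sensitivity_error_curve(hits, 4)
        errors = [e for e, _ in curve]
        # error climbs at FALSE hits (points 2 and 4), relaxes at TRUE hits
        assert errors == [0.0, 0.5, 1 / 3, 0.5]
        assert errors[1] > errors[0] and errors[3] > errors[2]

    def test_no_true_relations_rejected(self):
        with pytest.raises(BenchmarkError):
            sensitivity_error_curve([(1.0, FALSE)], 0)

    def test_sensitivity_at_error_threshold(self):
        curve = [(0.0, 0.2), (0.1, 0.45), (0.3, 0.6)]
        assert sensitivity_at_error(curve, 0.10) == 0.45
        assert sensitivity_at_error(curve, 0.05) == 0.2

    def test_dedupe_keeps_best_per_unordered_pair(self):
        hits = [("a", "b", 3.0), ("b", "a", 5.0), ("a", "a", 99.0), ("a", "c", 1.0)]
        deduped = dedupe_hits(hits)
        assert deduped == [("b", "a", 5.0), ("a", "c", 1.0)]

    def test_roc_auc_separable(self):
        assert roc_auc([3, 4, 5], [0, 1, 2]) == 1.0
        assert roc_auc([1], [1]) == 0.5


class TestCompose:
    def test_identity_composition(self):
        ident = [(k, k) for k in range(1, 6)]
        assert compose_alignments(ident, ident, ident) == ident

    def test_missing_profile_column_drops_pairs(self):
        ident = [(k, k) for k in range(1, 6)]
        pp = [(k, k) for k in range(1, 6) if k != 3]
        out = compose_alignments(ident, pp, ident)
        assert (3, 3) not in out and len(out) == 4

    def test_empty_profile_alignment_annihilates(self):
        ident = [(k, k) for k in range(1, 6)]
        assert compose_alignments(ident, [], ident) == []

    def test_offset_maps_compose(self):
        seq_to_p = [(r, r + 2) for r in range(1, 4)]   # residue r -> column r+2
        pp = [(c, c + 1) for c in range(3, 6)]          # P col -> Q col
        q_to_seq = [(c, c - 3) for c in range(4, 7)]    # Q col -> residue c-3
        assert compose_alignments(seq_to_p, pp, q_to_seq) == [
            (1, 1), (2, 2), (3, 3)
        ]

    def test_non_monotone_mapping_rejected(self):
        ident = [(k, k) for k in range(1, 4)]
        with pytest.raises(ContractViolation):
            compose_alignments([(1, 2), (2, 2)], ident, ident)


class TestAccuracy:
    def test_definitional_arithmetic(self):
        reference = ReferenceAlignment([(k, k) for k in range(1, 11)])
        test = [(k, k) for k in range(1, 5)] + [(k, k + 1) for k in range(5, 9)]
        developer, modeller = alignment_accuracy(test, reference)
        assert developer == pytest.approx(0.5)  # 4 correct of 8 in region
        assert modeller == pytest.approx(0.4)   # 4 correct of 10 reference

    def test_identity_scores_one_one(self):
        reference = ReferenceAlignment([(k, k) for k in range(1, 8)])
        assert alignment_accuracy(list(reference.pairs), reference) == (1.0, 1.0)

    def test_empty_test_scores_zero(self):
        reference = ReferenceAlignment([(1, 1), (2, 2)])
        assert alignment_accuracy([], reference) == (0.0, 0.0)

    def test_pairs_outside_reference_region_excluded_from_developer(self):
        reference = ReferenceAlignment([(5, 5), (6, 6), (7, 7)])
        test = [(1, 1), (5, 5), (6, 6)]  # (1,1) outside the overlap region
        developer, modeller = alignment_accuracy(test, reference)
        assert developer == pytest.approx(1.0)
        assert modeller == pytest.approx(2 / 3)

    def test_empty_reference_rejected(self):
        with pytest.raises(BenchmarkError):
            alignment_accuracy([(1, 1)], ReferenceAlignment([]))

    def test_reference_from_aligned_strings(self):
        ref = reference_from_aligned_pair("AC-DE", "A-GDE")
        assert ref.pairs == [(1, 1), (3, 3), (4, 4)]


class TestTuner:
    @staticmethod
    def score_fn_factory(informative_only_conservation):
        """Toy benchmark: conservation separates, hydro/SS are pure noise."""
        rng = np.random.default_rng(0)
        n_true, n_false = 12, 30
        cons_true = rng.normal(8, 1, n_true)
        cons_false = rng.normal(2, 1, n_false)
        noise_true = rng.normal(0, 4, n_true)
        noise_false = rng.normal(0, 4, n_false)

        def score_fn(params):
            hits = []
            scale = params.Wh + params.Ws
            for k in range(n_true):
                hits.append((params.Wc * cons_true[k] + scale * noise_true[k], TRUE))
            for k in range(n_false):
                hits.append((params.Wc * cons_false[k] + scale * noise_false[k], FALSE))
            return hits, n_true

        return score_fn

    def test_single_point_grid(self):
        p = ScoringParams()
        best, table = tune_parameters(self.score_fn_factory(True), [p])
        assert best is p and len(table) == 1

    def test_duplicate_points_collapse(self):
        p = ScoringParams()
        _, table = tune_parameters(self.score_fn_factory(True), [p, replace(p)])
        assert len(table) == 1

    def test_noise_terms_driven_to_zero(self):
        grid = [
            ScoringParams(Wh=wh, Ws=ws)
            for wh in (0.0, 0.5, 1.0)
            for ws in (0.0, 0.5, 1.0)
        ]
        best, _ = tune_parameters(self.score_fn_factory(True), grid)
        assert best.Wh == 0.0 and best.Ws == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(AlignHushError):
            tune_parameters(self.score_fn_factory(True), [])
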