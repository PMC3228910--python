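import pytest

from litcooc import (
    GoldInteraction,
    ValidationRecord,
    confirmed_keys,
    filter_gold,
    format_score_report,
    format_strata_report,
    load_gold,
    load_validations,
    pool_truth,
    save_validations,
    score,
    stratify_recall,
)
from litcooc.evalbench import GoldFormatError, ValidationConflictError


def gold(pmid, a, b, **flags):
    pair = tuple(sorted((a, b)))
    return GoldInteraction(pmid=str(pmid), pair=pair, **flags)


def truth_of(n):
    return [gold(i, "a", "b") for i in range(n)]


def preds_hitting(truth, n_true, n_false, cooc_type=1):
    preds = {g.key: cooc_type for g in truth[:n_true]}
    for i in range(n_false):
        preds[(f"fp{i}", ("x", "y"))] = cooc_type
    return preds


GOLD_TSV = """pmid\tterm1\tterm2\tis_self\tnon_gene_symbol\tboth_in_dictionary\tboth_detected\tcomplex_sentence
1\tAbeta\tSNCA\t0\t0\t1\t1\t0
2\tAPP\tAPP\t\t0\t1\t\t0
3\tTau complex\tAPP\t0\t1\t\t\t
"""


class TestLoadGold:
    def test_three_rows(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(GOLD_TSV)
        load = load_gold(path)
        assert len(load) == 3
        assert load.duplicates == 0

    def test_self_pair_flagged(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(GOLD_TSV)
        rec = next(r for r in load_gold(path) if r.pmid == "2")
        assert rec.is_self is True

    def test_terms_normalized_like_tagger_keys(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(GOLD_TSV)
        rec = next(r for r in load_gold(path) if r.pmid == "3")
        assert rec.pair == ("app", "tau complex")

    def test_duplicates_collapsed_and_counted(self, tmp_path):
        rows = "pmid\tterm1\tterm2\n1\tA\tB\n1\tB\tA\n2\tA\tB\n1\tA\tC\n1\ta\tb\n"
        path = tmp_path / "g.tsv"
        path.write_text(rows)
        load = load_gold(path)
        assert len(load) == 3
        assert load.duplicates == 2

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("pmid\tterm1\n1\tA\n")
        with pytest.raises(GoldFormatError, match="term2"):
            load_gold(path)

    def test_malformed_flag_names_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("pmid\tterm1\tterm2\tis_self\n1\tA\tB\tmaybe\n")
        with pytest.raises(GoldFormatError, match="line 2"):
            load_gold(path)


class TestFilterGold:
    def test_self_and_non_gene_excluded(self):
        records = (
            [gold(i, "a", "b") for i in range(7)]
            + [gold(10, "s", "s", is_self=True), gold(11, "t", "t", is_self=True)]
            + [gold(12, "a", "cplx", non_gene_symbol=True)]
        )
        retained, report = filter_gold(records)
        assert len(retained) == 7
        assert report == {"total": 10, "self": 2, "non_gene_symbol": 1, "retained": 7}

    def test_no_flags_all_retained(self):
        retained, report = filter_gold(truth_of(4))
        assert len(retained) == 4 and report["retained"] == 4

    def test_all_excluded(self):
        records = [gold(i, "s", "s", is_self=True) for i in range(10)]
        retained, report = filter_gold(records)
        assert retained == [] and report["total"] == 10 and report["self"] == 10


class TestPoolTruth:
    def test_gold_plus_confirmed_novel(self):
        pooled = pool_truth(
            truth_of(201), [(f"n{i}", ("p", "q")) for i in range(24)]
        )
        assert len(pooled) == 225

    def test_overlap_counted_once(self):
        base = truth_of(5)
        pooled = pool_truth(base, [base[0].key, ("new", ("x", "y"))])
        assert len(pooled) == 6

    def test_empty_confirmations(self):
        assert len(pool_truth(truth_of(3))) == 3


class TestScore:
    def test_printed_type1_row(self):
        truth = truth_of(225)
        r = score(truth, preds_hitting(truth, 56, 14), 1)
        assert (r.tp, r.n_predictions, r.truth_size) == (56, 70, 225)
        assert r.recall_pct == 25 and r.precision_pct == 80

    def test_printed_type2_and_type3_rows(self):
        truth = truth_of(225)
        preds = preds_hitting(truth, 56, 14, 1)
        preds.update(preds_hitting(truth, 76, 0, 2))
        for i in range(109 - 70 - (76 - 56)):
            preds[(f"fp2_{i}", ("x", "y"))] = 2
        preds.update({g.key: min(preds.get(g.key, 3), 3) for g in truth[:90]})
        for i in range(136 - 109 - (90 - 76)):
            preds[(f"fp3_{i}", ("x", "y"))] = 3
        r2 = score(truth, preds, 2)
        assert (r2.tp, r2.n_predictions) == (76, 109)
        assert r2.recall_pct == 34 and r2.precision_pct == 70
        r3 = score(truth, preds, 3)
        assert (r3.tp, r3.n_predictions) == (90, 136)
        assert r3.recall_pct == 40 and r3.precision_pct == 66

    def test_cumulative_counts_nest(self):
        truth = truth_of(50)
        preds = {g.key: (i % 3) + 1 for i, g in enumerate(truth)}
        results = [score(truth, preds, t) for t in (1, 2, 3)]
        for a, b in zip(results, results[1:]):
            assert a.tp <= b.tp and a.n_predictions <= b.n_predictions

    def test_zero_predictions_precision_missing_not_zero(self):
        r = score(truth_of(10), {}, 1)
        assert r.recall == 0.0
        assert r.precision is None and r.precision_pct is None

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            score([], {("1", ("a", "b")): 1}, 1)

    def test_report_contains_printed_percentages(self):
        truth = truth_of(225)
        text = format_score_report([score(truth, preds_hitting(truth, 56, 14), 1)])
        assert "56/225 (25%)" in text and "56/70 (80%)" in text


class TestStratifiedRecall:
    def make_truth(self):
        # 95 not-complex detected, 42 complex detected, 32 in-dictionary
        # only, 56 out-of-dictionary: strata nest 225 > 169 > 137 > 95
        truth = []
        for i in range(95):
            truth.append(gold(f"a{i}", "a", "b", both_in_dictionary=True,
                              both_detected=True, complex_sentence=False))
        for i in range(42):
            truth.append(gold(f"b{i}", "a", "b", both_in_dictionary=True,
                              both_detected=True, complex_sentence=True))
        for i in range(32):
            truth.append(gold(f"c{i}", "a", "b", both_in_dictionary=True,
                              both_detected=False, complex_sentence=True))
        for i in range(56):
            truth.append(gold(f"d{i}", "a", "b", both_in_dictionary=False,
                              both_detected=False))
        return truth

    def test_printed_not_complex_row(self):
        truth = self.make_truth()
        preds = {g.key: 3 for g in truth[:90]}  # 90 hits, all not-complex
        r = stratify_recall(truth, preds, 3, "not_complex")
        assert (r.tp, r.truth_size) == (90, 95)
        assert r.recall_pct == 95

    def test_nested_strata_recall_non_decreasing(self):
        truth = self.make_truth()
        preds = {g.key: 1 for g in truth[:90]}
        recalls = [
            stratify_recall(truth, preds, 1, s).recall
            for s in ("all", "both_in_dictionary", "both_detected", "not_complex")
        ]
        assert recalls == sorted(recalls)

    def test_stratum_all_equals_plain_score(self):
        truth = truth_of(40)
        preds = preds_hitting(truth, 10, 5)
        assert stratify_recall(truth, preds, 1, "all").recall == \
            score(truth, preds, 1).recall

    def test_unknown_flags_excluded_and_counted(self):
        truth = truth_of(10) + [
            gold("k", "a", "b", both_detected=True), gold("m", "a", "b",
                                                          both_detected=True)
        ]
        r = stratify_recall(truth, {}, 1, "both_detected")
        assert r.truth_size == 2
        assert r.unknown_excluded == 10

    def test_empty_stratum_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            stratify_recall(truth_of(5), {}, 1, "both_detected")

    def test_strata_report_shape(self):
        truth = self.make_truth()
        preds = {g.key: 1 for g in truth[:56]}
        rows = [
            stratify_recall(truth, preds, 1, s)
            for s in ("all", "both_in_dictionary", "both_detected", "not_complex")
        ]
        text = format_strata_report(rows)
        assert "Type 1" in text
        assert "56/225 (25%)" in text and "56/95 (59%)" in text


class TestValidations:
    def records(self):
        return [
            ValidationRecord("1", ("a", "b"), "validated", "2026-01-01T10:00:00"),
            ValidationRecord("1", ("a", "c"), "rejected", "2026-01-01T11:00:00"),
            ValidationRecord("2", ("a", "b"), "validated", "2026-01-02T09:00:00"),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "v.tsv"
        save_validations(self.records(), path)
        assert set(load_validations(path)) == set(self.records())

    def test_later_record_supersedes(self, tmp_path):
        path = tmp_path / "v.tsv"
        save_validations(
            self.records()
            + [ValidationRecord("1", ("a", "b"), "rejected", "2026-01-03T00:00:00")],
            path,
        )
        eff = {r.key: r.status for r in load_validations(path)}
        assert eff[("1", ("a", "b"))] == "rejected"

    def test_same_timestamp_conflict_raises(self, tmp_path):
        path = tmp_path / "v.tsv"
        save_validations(
            [
                ValidationRecord("1", ("a", "b"), "validated", "2026-01-01T00:00:00"),
                ValidationRecord("1", ("a", "b"), "rejected", "2026-01-01T00:00:00"),
            ],
            path,
        )
        with pytest.raises(ValidationConflictError):
            load_validations(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "v.tsv"
        save_validations([], path)
        assert load_validations(path) == []

    def test_confirmed_keys_feed_pooling(self):
        keys = confirmed_keys(self.records())
        assert keys == {("1", ("a", "b")), ("2", ("a", "b"))}
        # gold already holds (pmid 1, (a, b)): the union counts it once
        pooled = pool_truth(truth_of(2), keys)
        assert len(pooled) == 3

    def test_bad_status_rejected(self):
        with pytest.raises(ValueError):
            ValidationRecord("1", ("a", "b"), "maybe", "2026-01-01T00:00:00")
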