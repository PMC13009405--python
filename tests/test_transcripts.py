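"""Scoring-rule tests: lemmatization, checklist (CWF) scoring with the
repetition/perseveration exclusions, CIU counting, and the response
matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from discourselsm.irt import ItemResponseMatrix
from discourselsm.transcripts import (Checklist, ChecklistItem, CWFResult,
                                      Token, Transcript, count_cius,
                                      normalize_token, read_chat_lite,
                                      read_checklist, read_transcript_tsv,
                                      response_matrix, score_cwf, word_count,
                                      write_checklist, write_transcript_tsv)
from conftest import make_tokens


class TestNormalize:
    @pytest.mark.parametrize("surface,lemma", [
        ("cookie", "cookie"),          # identity
        ("Cookie,", "cookie"),         # case + punctuation
        ("cookies", "cookie"),         # -ie lemma plural
        ("stealing", "steal"),         # plain -ing
        ("taking", "take"),            # -ing with e-restoration
        ("children", "child"),         # irregular table
        ("took", "take"),              # irregular verb
        ("dishes", "dish"),            # -es after sibilant
        ("ladies", "lady"),            # -ies -> -y
        ("washed", "wash"),            # -ed
        ("running", "run"),            # consonant undoubling
        ("falls", "fall"),             # -s
        ("is", "is"),                  # short word untouched
        ("glass", "glass"),            # -ss not stripped
    ])
    def test_rules(self, surface, lemma):
        assert normalize_token(surface) == lemma

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_token("")


class TestScoreCWF:
    def test_empty_transcript(self, toy_checklist):
        res = score_cwf(Transcript(participant_id="p0"), toy_checklist)
        assert res.total == 0
        assert res.audit == ()

    def test_worked_example(self, toy_checklist):
        # "the boy is stealing cookies and he took a cookie cookie"
        words = "the boy is stealing cookies and he took a cookie cookie".split()
        tr = Transcript("p1", make_tokens(words))
        res = score_cwf(tr, toy_checklist)
        assert res.total == 4
        assert res.per_item_counts == {"cookie": 2, "steal": 2, "fall": 0}
        kinds = {(pos, kind) for pos, _, kind in res.audit}
        assert (3, "inflected") in kinds   # stealing
        assert (4, "inflected") in kinds   # cookies
        assert (7, "synonym") in kinds     # took -> take -> steal
        assert (9, "lemma") in kinds       # cookie
        assert res.excluded == ((10, "immediate_repetition"),)

    def test_each_lemma_once_distinct_phrases(self, toy_checklist):
        words = ["cookie", "steal", "fall"]
        tr = Transcript("p2", make_tokens(words, phrase_ids=[0, 1, 2]))
        res = score_cwf(tr, toy_checklist)
        assert res.total == 3
        assert all(kind == "lemma" for _, _, kind in res.audit)

    def test_perseveration_third_consecutive(self, toy_checklist):
        tr = Transcript("p3", make_tokens(["cookie", "cookie", "cookie", "cookie"]))
        res = score_cwf(tr, toy_checklist)
        assert res.total == 1
        reasons = [r for _, r in res.excluded]
        assert reasons == ["immediate_repetition", "perseveration", "perseveration"]

    def test_reuse_in_later_phrase_counts(self, toy_checklist):
        tr = Transcript("p4", make_tokens(["cookie", "cookie"], phrase_ids=[0, 1]))
        assert score_cwf(tr, toy_checklist).total == 2

    def test_filler_transparency(self, toy_checklist):
        # a filler between two identical matches does not break adjacency
        tr = Transcript("p5", make_tokens(
            ["cookie", "um", "cookie"],
            flags=[frozenset(), frozenset({"filler"}), frozenset()]))
        res = score_cwf(tr, toy_checklist)
        assert res.total == 1
        assert res.excluded[0][1] == "immediate_repetition"

    def test_contentful_word_resets_adjacency(self, toy_checklist):
        tr = Transcript("p6", make_tokens(["cookie", "nice", "cookie"]))
        assert score_cwf(tr, toy_checklist).total == 2

    def test_unintelligible_never_matches(self, toy_checklist):
        tr = Transcript("p7", make_tokens(
            ["cookie"], flags=[frozenset({"unintelligible"})]))
        assert score_cwf(tr, toy_checklist).total == 0

    def test_case_and_punctuation_invariance(self, toy_checklist):
        plain = Transcript("p8", make_tokens(["cookie", "steal", "fall"]))
        noisy = Transcript("p8", make_tokens(["Cookie,", "STEAL!", "fall."]))
        assert score_cwf(plain, toy_checklist).total == score_cwf(noisy, toy_checklist).total

    def test_audit_reconstructs_counts(self, toy_checklist, small_cohort):
        for tr in small_cohort.transcripts[:10]:
            res = score_cwf(tr, small_cohort.checklist)
            rebuilt = {}
            for _, item_id, _ in res.audit:
                rebuilt[item_id] = rebuilt.get(item_id, 0) + 1
            nonzero = {k: v for k, v in res.per_item_counts.items() if v}
            assert rebuilt == nonzero


class TestCIUAndWordCount:
    def test_all_fillers_zero(self):
        tr = Transcript("p0", make_tokens(["um"] * 5, flags=[frozenset({"filler"})] * 5))
        assert count_cius(tr) == 0

    def test_mixed_exclusions(self):
        # 10 tokens: 2 filler, 1 unintelligible, 1 immediate repetition, 6 clean -> 6
        words = ["um", "boy", "steals", "uh", "xxx", "cookie", "cookie", "mother", "washes", "dish"]
        flags = [frozenset({"filler"}), frozenset(), frozenset(), frozenset({"filler"}),
                 frozenset({"unintelligible"}), frozenset(), frozenset(),
                 frozenset(), frozenset(), frozenset()]
        tr = Transcript("p1", make_tokens(words, flags=flags))
        assert count_cius(tr) == 6

    def test_clean_distinct_tokens(self):
        words = ["boy", "girl", "mother", "sink"]
        tr = Transcript("p2", make_tokens(words))
        assert count_cius(tr) == 4
        assert word_count(tr) == 4

    def test_word_count_rules(self):
        tr = Transcript("p3", make_tokens(
            ["boy", "xxx", "um", "blick", "girl", "water"],
            flags=[frozenset(), frozenset({"unintelligible"}), frozenset({"filler"}),
                   frozenset({"non_word"}), frozenset(), frozenset()]))
        assert word_count(tr) == 4  # fillers count; xxx and non-word do not
        assert word_count(Transcript("p4")) == 0

    def test_word_count_dominates_ciu(self, small_cohort):
        for tr in small_cohort.transcripts:
            assert word_count(tr) >= count_cius(tr)


class TestResponseMatrix:
    def _result(self, counts):
        audit = tuple((i, k, "lemma") for i, (k, v) in enumerate(counts.items()) if v)
        return CWFResult(per_item_counts=counts, total=sum(counts.values()),
                         audit=audit, excluded=())

    def test_dichotomization(self):
        checklist = Checklist(items=(
            ChecklistItem(item_id="a", lemma="sink"),
            ChecklistItem(item_id="b", lemma="stool"),
        ))
        m = response_matrix([self._result({"a": 0, "b": 3})], checklist)
        assert m.data.tolist() == [[0, 1]]

    def test_degenerate_columns_dropped_for_irt(self):
        items = tuple(ChecklistItem(item_id=f"i{j:02d}", lemma=f"item{j:02d}")
                      for j in range(22))
        checklist = Checklist(items=items)
        results = []
        for i in range(10):
            counts = {}
            for j, it in enumerate(items):
                if j < 3:
                    counts[it.item_id] = 0       # all-zero columns
                elif j < 5:
                    counts[it.item_id] = 1       # all-one columns
                else:
                    counts[it.item_id] = (i + j) % 2  # guaranteed mixed
            results.append(self._result(counts))
        m = response_matrix(results, checklist, for_irt=True)
        assert len(m.items) == 17
        assert len(m.dropped_items) == 5
        m_raw = response_matrix(results, checklist, for_irt=False)
        assert len(m_raw.items) == 22

    def test_empty_results_rejected(self, toy_checklist):
        with pytest.raises(ValueError):
            response_matrix([], toy_checklist)


class TestIO:
    def test_transcript_roundtrip(self, tmp_path, small_cohort):
        tr = small_cohort.transcripts[0]
        path = tmp_path / "t.tsv"
        write_transcript_tsv(tr, path)
        back = read_transcript_tsv(path, tr.participant_id)
        assert back.tokens == tr.tokens

    def test_checklist_roundtrip(self, tmp_path, toy_checklist):
        path = tmp_path / "c.json"
        write_checklist(toy_checklist, path)
        back = read_checklist(path)
        assert back.items == toy_checklist.items

    def test_chat_lite(self, tmp_path, toy_checklist):
        text = "&-um the boy is stealing cookies\nxxx he took a cookie [x 2]\n"
        p = tmp_path / "p9.cha"
        p.write_text(text)
        tr = read_chat_lite(p)
        assert tr.participant_id == "p9"
        assert tr.tokens[0].flags == frozenset({"filler"})
        assert tr.tokens[0].phrase_id == 0
        assert tr.tokens[6].surface == "xxx"
        surfaces = [t.surface for t in tr.tokens]
        assert surfaces.count("cookie") == 2  # [x 2] expansion
        # the scoring rules then apply as usual
        assert score_cwf(tr, toy_checklist).total == 4


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hst.lists(
    hst.tuples(
        hst.sampled_from(["cookie", "steal", "take", "fall", "boy", "the", "um", "nice"]),
        hst.sampled_from([frozenset(), frozenset({"filler"}), frozenset({"off_topic"})]),
        hst.integers(min_value=0, max_value=2)),
    max_size=25))
def test_cwf_never_exceeds_word_count(tokens_spec):
    """CWF <= word count on arbitrary flagged token streams."""
    checklist = Checklist(items=(
        ChecklistItem(item_id="cookie", lemma="cookie"),
        ChecklistItem(item_id="steal", lemma="steal", synonyms=frozenset({"take"})),
        ChecklistItem(item_id="fall", lemma="fall"),
    ))
    tokens = tuple(Token(position=i, surface=w, flags=f, phrase_id=p)
                   for i, (w, f, p) in enumerate(tokens_spec))
    tr = Transcript(participant_id="px", tokens=tokens)
    assert score_cwf(tr, checklist).total <= word_count(tr)
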