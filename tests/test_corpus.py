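import json

import pytest
from hypothesis import given, settings, strategies as st

from belex.bel import BELStatement, BELTerm, parse_statement
from belex.corpus import (
    AlignmentError,
    AnnotatedSentence,
    CorpusFormatError,
    EntityMention,
    FD_WINDOW,
    align_identifiers,
    anonymize,
    build_function_instances,
    build_relation_instances,
    read_corpus,
    tokenize,
    write_corpus,
)
from conftest import EXAMPLE_STATEMENT, EXAMPLE_TEXT


class TestTokenize:
    def test_strips_edge_punctuation(self):
        assert tokenize("PP1c activity (K(i) = 2.9).") == ["PP1c", "activity", "K(i", "2.9"]

    def test_worked_sentence_token_positions(self):
        tokens = tokenize(EXAMPLE_TEXT)
        assert tokens.index("inhibitor") - tokens.index("AKAP220") == 5
        assert tokens.index("inhibitor") - tokens.index("PP1c") == -2


class TestCorpusIO:
    def test_round_trip_through_file(self, tmp_path, example_sentence):
        path = tmp_path / "corpus.jsonl"
        write_corpus([example_sentence], path)
        loaded = read_corpus(path)
        assert len(loaded) == 1
        s = loaded[0]
        assert len(s.mentions) == 2
        assert len(s.gold_statements) == 1
        assert s.gold_statements[0] == parse_statement(EXAMPLE_STATEMENT)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_corpus(path) == []

    def test_schema_violation_names_line_and_field(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"id": "s1"}\n')
        with pytest.raises(CorpusFormatError, match="line 1.*tokens"):
            read_corpus(path)

    def test_unparseable_statement_reported_with_string(self, tmp_path):
        rec = {"id": "s1", "tokens": ["a"], "mentions": [], "statements": ["p(HGNC:"]}
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(rec) + "\n")
        with pytest.raises(CorpusFormatError, match=r"p\(HGNC:"):
            read_corpus(path)

    def test_statement_without_mention_is_alignment_error(self, tmp_path):
        rec = {
            "id": "s1",
            "tokens": ["X9", "rises"],
            "mentions": [
                {"start": 0, "end": 1, "surface": "X9", "entity_class": "gene_protein",
                 "ns_id": "HGNC:X9"}
            ],
            "statements": ["p(HGNC:X9) increases p(HGNC:Y9)"],
        }
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(rec) + "\n")
        with pytest.raises(AlignmentError, match="HGNC:Y9"):
            read_corpus(path)


class TestAlignment:
    LEXICON = {"HGNC:AKAP11": ["AKAP220"], "HGNC:PPP1CC": ["PP1c"]}

    def test_worked_example_alignment(self):
        mentions, unaligned = align_identifiers(
            EXAMPLE_TEXT, ["HGNC:AKAP11", "HGNC:PPP1CC"], self.LEXICON
        )
        assert unaligned == []
        by_id = {m.ns_id: m for m in mentions}
        assert by_id["HGNC:AKAP11"].surface == "AKAP220"
        assert by_id["HGNC:PPP1CC"].surface == "PP1c"

    def test_exact_match_beats_near_match(self):
        lexicon = {"SYN:1": ["GPA1"]}
        mentions, _ = align_identifiers("GPA1 resembles GPA2 here", ["SYN:1"], lexicon)
        assert mentions[0].surface == "GPA1"
        assert mentions[0].start == 0

    def test_zero_cutoff_requires_exact_match(self):
        lexicon = {"SYN:1": ["GPA1"]}
        _, unaligned = align_identifiers("only GPA9 appears", ["SYN:1"], lexicon, cutoff=0.0)
        assert unaligned == ["SYN:1"]

    def test_assigned_spans_do_not_overlap(self):
        lexicon = {"SYN:1": ["alpha beta"], "SYN:2": ["beta gamma"]}
        mentions, unaligned = align_identifiers(
            "alpha beta gamma", ["SYN:1", "SYN:2"], lexicon
        )
        spans = [(m.start, m.end) for m in mentions]
        for i, a in enumerate(spans):
            for b in spans[i + 1 :]:
                assert a[1] <= b[0] or b[1] <= a[0]


class TestAnonymize:
    def test_worked_sentence_placeholders(self, example_sentence):
        a = anonymize(example_sentence)
        assert "GENE_1" in a.tokens and "GENE_2" in a.tokens
        assert a.tokens.index("GENE_1") < a.tokens.index("GENE_2")
        assert a.tokens[a.tokens.index("GENE_1") + 1] == "fragment"

    def test_no_mentions_unchanged(self):
        s = AnnotatedSentence("s", ["nothing", "here"])
        assert anonymize(s).tokens == ["nothing", "here"]

    def test_numbering_follows_surface_order(self):
        s = AnnotatedSentence(
            "s",
            ["A1", "meets", "B2", "then", "C3"],
            mentions=[
                EntityMention(4, 5, "C3", "gene_protein", "SYN:3"),
                EntityMention(0, 1, "A1", "gene_protein", "SYN:1"),
                EntityMention(2, 3, "B2", "gene_protein", "SYN:2"),
            ],
        )
        a = anonymize(s)
        assert a.tokens == ["GENE_1", "meets", "GENE_2", "then", "GENE_3"]
        assert [m.ns_id for m in a.mentions] == ["SYN:1", "SYN:2", "SYN:3"]

    def test_mixed_classes_counted_separately(self):
        s = AnnotatedSentence(
            "s",
            ["A1", "and", "C9", "and", "A2"],
            mentions=[
                EntityMention(0, 1, "A1", "gene_protein", "SYN:1"),
                EntityMention(2, 3, "C9", "chemical", "SYN:2"),
                EntityMention(4, 5, "A2", "gene_protein", "SYN:3"),
            ],
        )
        assert anonymize(s).tokens == ["GENE_1", "and", "CHEM_1", "and", "GENE_2"]

    def test_multi_token_span_collapses_and_remaps(self):
        s = AnnotatedSentence(
            "s",
            ["the", "big", "complex", "name", "binds", "X1"],
            mentions=[
                EntityMention(1, 4, "big complex name", "bioprocess", "SYN:1"),
                EntityMention(5, 6, "X1", "gene_protein", "SYN:2"),
            ],
        )
        a = anonymize(s)
        assert a.tokens == ["the", "BP_1", "binds", "GENE_1"]
        assert a.mentions[1].start == 3

    def test_reversible_via_placeholder_table(self, example_sentence):
        a = anonymize(example_sentence)
        table = {m.placeholder: m.ns_id for m in a.mentions}
        gold_ids = {t.ns_id for s in a.gold_statements for t in (s.subject, s.object)}
        assert gold_ids == set(table.values())

    def test_overlapping_mentions_rejected(self):
        s = AnnotatedSentence(
            "s",
            ["a", "b", "c"],
            mentions=[
                EntityMention(0, 2, "a b", "gene_protein", "SYN:1"),
                EntityMention(1, 3, "b c", "gene_protein", "SYN:2"),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            anonymize(s)


def _synthetic_sentence(n_mentions: int, relations: list[tuple[int, int, str]]):
    """A bare sentence with n placeholder-ready mentions and the given gold
    relations as (subject_idx, object_idx, relation) triples."""
    tokens = []
    mentions = []
    for k in range(n_mentions):
        tokens.extend(["filler", f"E{k}"])
        mentions.append(
            EntityMention(2 * k + 1, 2 * k + 2, f"E{k}", "gene_protein", f"SYN:{k}")
        )
    statements = [
        BELStatement(
            BELTerm("gene_protein", "SYN", str(a)),
            rel,
            BELTerm("gene_protein", "SYN", str(b)),
        )
        for a, b, rel in relations
    ]
    return AnnotatedSentence("s", tokens, mentions, statements)


class TestInstanceConstruction:
    def test_example_sentence_single_decreases_pair(self, example_sentence):
        a = anonymize(example_sentence)
        rel = build_relation_instances(a, mode="train")
        assert len(rel) == 1
        assert rel[0].label == "decreases"
        assert rel[0].subject_first is True

    def test_example_sentence_function_labels(self, example_sentence):
        a = anonymize(example_sentence)
        fd = build_function_instances(a, mode="train")
        assert [(i.placeholder, i.label) for i in fd] == [("GENE_1", "none"), ("GENE_2", "act")]

    def test_pair_count_without_gold(self):
        s = anonymize(_synthetic_sentence(4, []))
        instances = build_relation_instances(s, mode="train")
        assert len(instances) == 6
        assert all(i.label == "none" for i in instances)

    def test_single_mention_yields_no_pairs(self):
        s = anonymize(_synthetic_sentence(1, []))
        assert build_relation_instances(s, mode="train") == []

    def test_shared_subject_duplicates_kept(self):
        s = anonymize(
            _synthetic_sentence(4, [(0, 1, "increases"), (0, 2, "increases"), (0, 3, "decreases")])
        )
        fd = build_function_instances(s, mode="train")
        assert len(fd) == 6
        assert sum(1 for i in fd if i.placeholder == "GENE_1") == 3

    def test_test_mode_one_fd_instance_per_mention(self):
        s = anonymize(_synthetic_sentence(4, [(0, 1, "increases")]))
        fd = build_function_instances(s, mode="test")
        assert len(fd) == 4
        assert all(i.label == "none" and not i.probabilities for i in fd)

    def test_reversed_argument_order_recorded(self):
        s = anonymize(_synthetic_sentence(2, [(1, 0, "increases")]))
        (inst,) = build_relation_instances(s, mode="train")
        assert inst.label == "increases"
        assert inst.subject_first is False

    def test_conflicting_pair_labels_keep_first_and_warn(self):
        s = anonymize(
            _synthetic_sentence(2, [(0, 1, "increases"), (1, 0, "decreases")])
        )
        with pytest.warns(UserWarning, match="conflicting"):
            (inst,) = build_relation_instances(s, mode="train")
        assert inst.label == "increases"

    def test_window_never_exceeds_limit_and_contains_entity(self):
        tokens = [f"w{i}" for i in range(40)]
        s = AnnotatedSentence(
            "s",
            tokens,
            mentions=[EntityMention(20, 21, "w20", "gene_protein", "SYN:1"),
                      EntityMention(39, 40, "w39", "gene_protein", "SYN:2")],
        )
        fd = build_function_instances(anonymize(s), mode="test")
        for inst in fd:
            assert len(inst.tokens) <= FD_WINDOW
            assert inst.tokens[inst.entity_index] == inst.placeholder

    @settings(derandomize=True, max_examples=60)
    @given(n=st.integers(1, 6), data=st.data())
    def test_count_closed_forms(self, n, data):
        """n mentions -> n(n-1)/2 relation instances; m gold relations -> 2m
        train-mode function instances."""
        max_m = min(5, n * (n - 1) // 2)
        m = data.draw(st.integers(0, max_m)) if max_m else 0
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        chosen = data.draw(st.permutations(pairs))[:m] if pairs else []
        rels = [(a, b, "increases") for a, b in chosen]
        s = anonymize(_synthetic_sentence(n, rels))
        assert len(build_relation_instances(s, mode="train")) == n * (n - 1) // 2
        assert len(build_function_instances(s, mode="train")) == 2 * m
        positives = [i for i in build_relation_instances(s, mode="train") if i.label != "none"]
        assert len(positives) == m
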