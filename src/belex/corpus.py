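"""Annotated-corpus I/O and classifier-instance construction.

The corpus format is JSON-lines: one sentence record per line with an id,
the raw text, its token sequence, typed entity mentions (half-open token
spans plus ``namespace:identifier``), and gold BEL statements as strings.
Entity mentions are anonymized to typed placeholders (``GENE_1``, ``CHEM_1``,
...) before classification so the models see entity positions, not surface
names.

Two kinds of classifier instances are built from an anonymized sentence:

* relation instances — one per unordered mention pair, ``n(n-1)/2`` for a
  sentence with ``n`` mentions, labeled with the canonical causal relation
  of a gold statement linking the pair (``none`` otherwise);
* function instances — in training, one per entity participating in a gold
  binary statement (``2m`` instances for ``m`` positive relations, duplicates
  kept); in testing, one per mention.  Each carries a context window of at
  most 15 tokens centered on the placeholder.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib

from .bel import (
    BELComplex,
    BELStatement,
    BELTerm,
    canonicalize,
    parse_statement,
    serialize_statement,
)

__all__ = [
    "EntityMention",
    "AnnotatedSentence",
    "RelationInstance",
    "FunctionInstance",
    "CorpusFormatError",
    "AlignmentError",
    "tokenize",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "align_identifiers",
    "anonymize",
    "build_relation_instances",
    "build_function_instances",
    "FD_WINDOW",
    "PLACEHOLDER_PREFIXES",
]

FD_WINDOW = 15  # max tokens in a function-detection context window
_HALF_WINDOW = FD_WINDOW // 2

PLACEHOLDER_PREFIXES = {
    "gene_protein": "GENE",
    "chemical": "CHEM",
    "disease": "DIS",
    "bioprocess": "BP",
    "rna": "RNA",
}

# default namespace -> entity class guess used by lexicon alignment
NAMESPACE_CLASSES = {
    "HGNC": "gene_protein",
    "MGI": "gene_protein",
    "EGID": "gene_protein",
    "CHEBI": "chemical",
    "MESHC": "chemical",
    "MESHD": "disease",
    "GOBP": "bioprocess",
}


class CorpusFormatError(ValueError):
    """Schema violation in a corpus file; names the line and field."""


class AlignmentError(ValueError):
    """A statement references an identifier with no (unique) mention."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity occurrence as a half-open token span."""

    start: int
    end: int
    surface: str
    entity_class: str
    ns_id: str
    placeholder: str | None = None


@dataclass
class AnnotatedSentence:
    sentence_id: str
    tokens: list[str]
    mentions: list[EntityMention] = field(default_factory=list)
    gold_statements: list[BELStatement] = field(default_factory=list)
    text: str | None = None


@dataclass
class RelationInstance:
    """One unordered mention pair in an anonymized sentence."""

    sentence_id: str
    tokens: list[str]
    e1_index: int
    e2_index: int
    e1_placeholder: str
    e2_placeholder: str
    label: str = "none"  # canonical: none | increases | decreases
    subject_first: bool | None = None  # True if e1 was the statement subject
    probabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.e1_index < self.e2_index:
            raise ValueError("e1_index must precede e2_index")


@dataclass
class FunctionInstance:
    """One entity with its ≤15-token context window."""

    sentence_id: str
    tokens: list[str]
    entity_index: int
    placeholder: str
    label: str = "none"
    probabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.tokens) > FD_WINDOW:
            raise ValueError(f"window exceeds {FD_WINDOW} tokens")
        if not 0 <= self.entity_index < len(self.tokens):
            raise ValueError("entity_index outside window")


def tokenize(text: str) -> list[str]:
    """Whitespace split, then strip leading/trailing punctuation per token.

    Tokens that are pure punctuation are dropped.
    """
    out = []
    for raw in text.split():
        tok = raw.strip(string.punctuation)
        if tok:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# corpus file I/O


def _mention_from_record(rec: dict, lineno: int, n_tokens: int) -> EntityMention:
    for key in ("start", "end", "entity_class", "ns_id"):
        if key not in rec:
            raise CorpusFormatError(f"line {lineno}: mention missing field {key!r}")
    start, end = rec["start"], rec["end"]
    if not (isinstance(start, int) and isinstance(end, int) and 0 <= start < end <= n_tokens):
        raise CorpusFormatError(f"line {lineno}: mention span [{start}, {end}) out of range")
    if rec["entity_class"] not in PLACEHOLDER_PREFIXES:
        raise CorpusFormatError(
            f"line {lineno}: unknown entity_class {rec['entity_class']!r}"
        )
    return EntityMention(
        start=start,
        end=end,
        surface=rec.get("surface", ""),
        entity_class=rec["entity_class"],
        ns_id=rec["ns_id"],
        placeholder=rec.get("placeholder"),
    )


def _statement_ns_ids(s: BELStatement) -> list[str]:
    out = []
    for side in (s.subject, s.object):
        if isinstance(side, BELComplex):
            out.extend(m.ns_id for m in side.members)
        else:
            out.append(side.ns_id)
    return out


def _validate_sentence(s: AnnotatedSentence, lineno: int | None = None) -> None:
    where = f"line {lineno}: " if lineno is not None else ""
    spans = sorted((m.start, m.end) for m in s.mentions)
    for (a_start, a_end), (b_start, b_end) in zip(spans, spans[1:]):
        if b_start < a_end:
            raise CorpusFormatError(f"{where}overlapping mention spans")
    by_id: dict[str, int] = {}
    for m in s.mentions:
        by_id[m.ns_id] = by_id.get(m.ns_id, 0) + 1
    for stmt in s.gold_statements:
        for ns_id in _statement_ns_ids(stmt):
            if by_id.get(ns_id, 0) != 1:
                raise AlignmentError(
                    f"{where}statement references {ns_id!r} with "
                    f"{by_id.get(ns_id, 0)} matching mentions (need exactly 1)"
                )


def read_corpus(path: str | Path) -> list[AnnotatedSentence]:
    """Read a JSON-lines corpus file into validated sentences."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            for key in ("id", "tokens"):
                if key not in rec:
                    raise CorpusFormatError(f"line {lineno}: missing field {key!r}")
            tokens = rec["tokens"]
            if not isinstance(tokens, list) or not all(isinstance(t, str) for t in tokens):
                raise CorpusFormatError(f"line {lineno}: field 'tokens' must be a string list")
            mentions = [
                _mention_from_record(m, lineno, len(tokens))
                for m in rec.get("mentions", [])
            ]
            statements = []
            for text in rec.get("statements", []):
                try:
                    statements.append(parse_statement(text))
                except ValueError as exc:
                    raise CorpusFormatError(
                        f"line {lineno}: unparseable statement {text!r}: {exc}"
                    ) from exc
            sentence = AnnotatedSentence(
                sentence_id=str(rec["id"]),
                tokens=list(tokens),
                mentions=mentions,
                gold_statements=statements,
                text=rec.get("text"),
            )
            _validate_sentence(sentence, lineno)
            sentences.append(sentence)
    return sentences


def write_corpus(sentences: list[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "id": s.sentence_id,
                "text": s.text if s.text is not None else " ".join(s.tokens),
                "tokens": s.tokens,
                "mentions": [
                    {
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "entity_class": m.entity_class,
                        "ns_id": m.ns_id,
                        **({"placeholder": m.placeholder} if m.placeholder else {}),
                    }
                    for m in s.mentions
                ],
                "statements": [serialize_statement(st) for st in s.gold_statements],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_lexicon(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (``NS:identifier``, synonym) -> identifier synonym lists."""
    lexicon: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(f"line {lineno}: expected 2 tab-separated columns")
            lexicon.setdefault(parts[0], []).append(parts[1])
    return lexicon


def write_lexicon(lexicon: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ns_id in lexicon:
            for synonym in lexicon[ns_id]:
                fh.write(f"{ns_id}\t{synonym}\n")


# ---------------------------------------------------------------------------
# dictionary-search alignment


def _normalized_edit_distance(a: str, b: str) -> float:
    if not a and not b:
        return 0.0
    dist = edlib.align(a, b)["editDistance"]
    return dist / max(len(a), len(b))


def align_identifiers(
    sentence_text: str,
    identifiers: list[str],
    lexicon: dict[str, list[str]],
    *,
    cutoff: float = 0.3,
    max_span: int = 5,
    entity_classes: dict[str, str] | None = None,
) -> tuple[list[EntityMention], list[str]]:
    """Dictionary search: align each identifier to the sentence span that
    minimizes normalized edit distance to any of its lexicon synonyms.

    Candidate spans are contiguous token runs of length 1..``max_span``;
    a span is accepted only when its best normalized distance is <= ``cutoff``.
    Spans are assigned greedily best-score-first and never overlap.  Returns
    ``(mentions, unaligned_identifiers)``; mentions are sorted by position.
    """
    tokens = tokenize(sentence_text)
    candidates = []  # (score, identifier, start, end, surface)
    for ns_id in identifiers:
        synonyms = lexicon.get(ns_id, [])
        if not synonyms:
            continue
        for start in range(len(tokens)):
            for end in range(start + 1, min(start + max_span, len(tokens)) + 1):
                surface = " ".join(tokens[start:end])
                score = min(_normalized_edit_distance(surface, syn) for syn in synonyms)
                if score <= cutoff:
                    candidates.append((score, ns_id, start, end, surface))
    # best-score-first; ties broken by identifier order then position
    id_rank = {ns_id: k for k, ns_id in enumerate(identifiers)}
    candidates.sort(key=lambda c: (c[0], id_rank[c[1]], c[2], c[3]))
    taken: list[tuple[int, int]] = []
    assigned: dict[str, tuple[int, int, str]] = {}
    for score, ns_id, start, end, surface in candidates:
        if ns_id in assigned:
            continue
        if any(start < t_end and t_start < end for t_start, t_end in taken):
            continue
        assigned[ns_id] = (start, end, surface)
        taken.append((start, end))
    mentions = []
    unaligned = []
    classes = entity_classes or {}
    for ns_id in identifiers:
        if ns_id not in assigned:
            unaligned.append(ns_id)
            continue
        start, end, surface = assigned[ns_id]
        namespace = ns_id.split(":", 1)[0]
        entity_class = classes.get(ns_id, NAMESPACE_CLASSES.get(namespace, "gene_protein"))
        mentions.append(EntityMention(start, end, surface, entity_class, ns_id))
    mentions.sort(key=lambda m: m.start)
    return mentions, unaligned


# ---------------------------------------------------------------------------
# anonymization


def anonymize(s: AnnotatedSentence) -> AnnotatedSentence:
    """Replace each mention span by a typed placeholder token.

    Placeholders are numbered per entity class in left-to-right mention order
    (GENE_1, GENE_2, CHEM_1, ...).  Token indices of later mentions are
    remapped; every anonymized mention has a length-1 span.
    """
    ordered = sorted(s.mentions, key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping mentions in sentence {s.sentence_id}")
    counters: dict[str, int] = {}
    new_tokens: list[str] = []
    new_mentions: list[EntityMention] = []
    cursor = 0
    for m in ordered:
        new_tokens.extend(s.tokens[cursor : m.start])
        counters[m.entity_class] = counters.get(m.entity_class, 0) + 1
        placeholder = f"{PLACEHOLDER_PREFIXES[m.entity_class]}_{counters[m.entity_class]}"
        index = len(new_tokens)
        new_tokens.append(placeholder)
        new_mentions.append(replace(m, start=index, end=index + 1, placeholder=placeholder))
        cursor = m.end
    new_tokens.extend(s.tokens[cursor:])
    return AnnotatedSentence(
        sentence_id=s.sentence_id,
        tokens=new_tokens,
        mentions=new_mentions,
        gold_statements=list(s.gold_statements),
        text=s.text,
    )


# ---------------------------------------------------------------------------
# instance construction


def _binary_statements(s: AnnotatedSentence) -> list[BELStatement]:
    """Gold statements with two single-entity arguments (complex() excluded)."""
    return [
        st
        for st in s.gold_statements
        if isinstance(st.subject, BELTerm) and isinstance(st.object, BELTerm)
    ]


def _mention_by_ns_id(s: AnnotatedSentence) -> dict[str, EntityMention]:
    table = {}
    for m in s.mentions:
        table[m.ns_id] = m
    return table


def build_relation_instances(
    s: AnnotatedSentence, mode: str = "train"
) -> list[RelationInstance]:
    """All unordered mention pairs: exactly ``n(n-1)/2`` instances.

    In train mode the label is the canonical relation of the first gold
    statement linking the pair (in either argument order); conflicting labels
    for the same pair keep the first and warn.  In test mode labels are left
    unset (``none`` with ``subject_first=None``).
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    mentions = sorted(s.mentions, key=lambda m: m.start)
    if any(m.placeholder is None for m in mentions):
        raise ValueError("sentence must be anonymized first")
    pair_label: dict[frozenset[str], tuple[str, bool]] = {}
    if mode == "train":
        for st in _binary_statements(s):
            cst = canonicalize(st)
            key = frozenset((cst.subject.ns_id, cst.object.ns_id))
            if key in pair_label:
                if pair_label[key][0] != cst.relation:
                    warnings.warn(
                        f"sentence {s.sentence_id}: conflicting relation labels for pair "
                        f"{sorted(key)}; keeping the first",
                        stacklevel=2,
                    )
                continue
            pair_label[key] = (cst.relation, cst.subject.ns_id)
    instances = []
    for i, m1 in enumerate(mentions):
        for m2 in mentions[i + 1 :]:
            label, subject_first = "none", None
            if mode == "train":
                entry = pair_label.get(frozenset((m1.ns_id, m2.ns_id)))
                if entry is not None:
                    label = entry[0]
                    subject_first = entry[1] == m1.ns_id
            instances.append(
                RelationInstance(
                    sentence_id=s.sentence_id,
                    tokens=list(s.tokens),
                    e1_index=m1.start,
                    e2_index=m2.start,
                    e1_placeholder=m1.placeholder,
                    e2_placeholder=m2.placeholder,
                    label=label,
                    subject_first=subject_first,
                )
            )
    return instances


def context_window(tokens: list[str], index: int, width: int = FD_WINDOW) -> tuple[list[str], int]:
    """A window of at most ``width`` tokens centered on ``index``.

    Centering is half the width on each side, truncated at sentence
    boundaries; returns the window and the entity position within it.
    """
    half = width // 2
    start = max(0, index - half)
    end = min(len(tokens), index + half + 1)
    return tokens[start:end], index - start


def build_function_instances(
    s: AnnotatedSentence, mode: str = "train"
) -> list[FunctionInstance]:
    """Function-detection instances over ≤15-token context windows.

    Train mode: one instance per entity participating in a gold binary
    statement, labeled with its canonical function (``none`` when unwrapped)
    — ``2m`` instances for ``m`` positive relations, duplicates kept.
    Test mode: one unlabeled instance per mention.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    if any(m.placeholder is None for m in s.mentions):
        raise ValueError("sentence must be anonymized first")
    by_id = _mention_by_ns_id(s)
    instances = []
    if mode == "train":
        for st in _binary_statements(s):
            cst = canonicalize(st)
            for term in (cst.subject, cst.object):
                mention = by_id.get(term.ns_id)
                if mention is None:
                    raise AlignmentError(
                        f"sentence {s.sentence_id}: no mention for {term.ns_id!r}"
                    )
                window, entity_index = context_window(s.tokens, mention.start)
                instances.append(
                    FunctionInstance(
                        sentence_id=s.sentence_id,
                        tokens=window,
                        entity_index=entity_index,
                        placeholder=mention.placeholder,
                        label=term.function_label,
                    )
                )
    else:
        for mention in sorted(s.mentions, key=lambda m: m.start):
            window, entity_index = context_window(s.tokens, mention.start)
            instances.append(
                FunctionInstance(
                    sentence_id=s.sentence_id,
                    tokens=window,
                    entity_index=entity_index,
                    placeholder=mention.placeholder,
                )
            )
    return instances
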