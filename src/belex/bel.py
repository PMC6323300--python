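"""Data model, parser, serializer and canonical normalizer for a BEL subset.

The subset covered is the short-form OpenBEL 1.0 causal statement: a
namespaced entity abundance (``p``/``a``/``path``/``bp``/``r``), optionally
wrapped by one unary function (``act``, ``deg``, ``pmod``, ``sec``, ``tloc``
or an activity-family function such as ``kin``/``tscript``/``cat``), joined
to a second term by one of the four causal relations.  ``complex()`` with
multiple arguments is parsed into a dedicated multi-argument record but is
not a function-detection target.

Canonicalization collapses the label space to the one used by the
classifiers: ``directlyIncreases``/``directlyDecreases`` fold into
``increases``/``decreases`` and every activity-family function folds into
``act``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

__all__ = [
    "BELTerm",
    "BELComplex",
    "BELStatement",
    "BELParseError",
    "parse_statement",
    "parse_term",
    "serialize_statement",
    "serialize_term",
    "canonicalize",
    "canonicalize_relation",
    "canonicalize_function",
    "ENTITY_CLASSES",
    "ABUNDANCE_KEYWORDS",
    "RELATIONS",
    "FD_LABELS",
    "ACTIVITY_FAMILY",
]

# entity class -> surface abundance keyword
ABUNDANCE_KEYWORDS = {
    "gene_protein": "p",
    "chemical": "a",
    "disease": "path",
    "bioprocess": "bp",
    "rna": "r",
}
_KEYWORD_TO_CLASS = {v: k for k, v in ABUNDANCE_KEYWORDS.items()}
ENTITY_CLASSES = tuple(ABUNDANCE_KEYWORDS)

RELATIONS = ("increases", "decreases", "directlyIncreases", "directlyDecreases")
_RELATION_MAP = {
    "increases": "increases",
    "directlyIncreases": "increases",
    "decreases": "decreases",
    "directlyDecreases": "decreases",
}

# Activity-family functions folded into act() on canonicalization.  The set is
# configurable at call sites; this is the default.
ACTIVITY_FAMILY = frozenset(
    {"act", "kin", "tscript", "cat", "phos", "pep", "gtp", "ribo", "tport", "chap"}
)

# Unary function labels accepted by the parser; "complex" is parse-only and
# never a function-detection label.
KNOWN_FUNCTIONS = frozenset({"deg", "pmod", "sec", "tloc", "complex"}) | ACTIVITY_FAMILY

# Labels a function-detection classifier may carry (post-canonicalization).
FD_LABELS = ("none", "act", "deg", "pmod", "sec")

_BARE_IDENT_CHARS = frozenset(string.ascii_letters + string.digits + "_.-")


class BELParseError(ValueError):
    """Malformed BEL input; carries the character offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class BELTerm:
    """A namespaced entity abundance with an optional unary function wrapper."""

    entity_class: str
    namespace: str
    identifier: str
    function_label: str = "none"

    def __post_init__(self):
        if self.entity_class not in ABUNDANCE_KEYWORDS:
            raise ValueError(f"unknown entity class {self.entity_class!r}")
        if not self.namespace or not self.identifier:
            raise ValueError("namespace and identifier must be non-empty")
        if self.function_label != "none" and self.function_label not in KNOWN_FUNCTIONS:
            raise ValueError(f"unknown function label {self.function_label!r}")

    @property
    def ns_id(self) -> str:
        return f"{self.namespace}:{self.identifier}"


@dataclass(frozen=True)
class BELComplex:
    """A multi-argument ``complex()`` term.

    Parse-only: carried through for completeness but never a target of
    function detection (``supported_for_fd`` is always False).
    """

    members: tuple[BELTerm, ...]
    supported_for_fd: bool = False

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("BELComplex requires at least two members")


@dataclass(frozen=True)
class BELStatement:
    """``subject relation object`` where the relation is causal."""

    subject: BELTerm | BELComplex
    relation: str
    object: BELTerm | BELComplex

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.subject == self.object:
            raise ValueError("subject and object must be distinct terms")


class _Parser:
    """Recursive-descent parser over a single statement string."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> BELParseError:
        return BELParseError(message, self.pos)

    def skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str):
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def read_word(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] in _BARE_IDENT_CHARS:
            self.pos += 1
        if self.pos == start:
            raise self.error("expected a keyword or identifier")
        return self.text[start : self.pos]

    def read_identifier(self) -> str:
        self.skip_ws()
        quote = self.peek()
        if quote in ("'", '"'):
            self.pos += 1
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] != quote:
                self.pos += 1
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted identifier")
            ident = self.text[start : self.pos]
            self.pos += 1  # closing quote
            if not ident:
                raise self.error("empty quoted identifier")
            return ident
        return self.read_word()

    def parse_abundance(self, keyword: str) -> BELTerm:
        entity_class = _KEYWORD_TO_CLASS[keyword]
        self.skip_ws()
        self.expect("(")
        self.skip_ws()
        namespace = self.read_word()
        self.skip_ws()
        self.expect(":")
        identifier = self.read_identifier()
        self.skip_ws()
        self.expect(")")
        return BELTerm(entity_class, namespace, identifier)

    def parse_term(self, depth: int = 0) -> BELTerm | BELComplex:
        self.skip_ws()
        word_start = self.pos
        word = self.read_word()
        self.skip_ws()
        if self.peek() != "(":
            self.pos = word_start
            raise self.error(f"expected a term, got {word!r}")
        if word in _KEYWORD_TO_CLASS:
            self.pos = word_start
            word2 = self.read_word()
            return self.parse_abundance(word2)
        if word == "complex":
            if depth > 0:
                self.pos = word_start
                raise self.error("unsupported nesting: complex() inside a function")
            self.expect("(")
            members = [self._inner_abundance()]
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                members.append(self._inner_abundance())
                self.skip_ws()
            self.expect(")")
            if len(members) == 1:
                # single-argument complex degenerates to a wrapped term
                return replace(members[0], function_label="complex")
            return BELComplex(tuple(members))
        if word in KNOWN_FUNCTIONS:
            if depth > 0:
                self.pos = word_start
                raise self.error("unsupported nesting: functions nest at most one level")
            self.expect("(")
            inner = self.parse_term(depth + 1)
            if not isinstance(inner, BELTerm):
                raise self.error("unsupported nesting: complex() inside a function")
            if inner.function_label != "none":
                raise self.error("unsupported nesting: functions nest at most one level")
            self.skip_ws()
            self.expect(")")
            return replace(inner, function_label=word)
        self.pos = word_start
        raise self.error(f"unknown keyword {word!r}")

    def _inner_abundance(self) -> BELTerm:
        term = self.parse_term(depth=1)
        if not isinstance(term, BELTerm) or term.function_label != "none":
            raise self.error("complex() arguments must be bare abundances")
        return term

    def parse_relation(self) -> str:
        self.skip_ws()
        word_start = self.pos
        word = self.read_word()
        if word not in RELATIONS:
            self.pos = word_start
            raise self.error(f"expected a relation keyword, got {word!r}")
        return word

    def parse_statement(self) -> BELStatement:
        subject = self.parse_term()
        relation = self.parse_relation()
        obj = self.parse_term()
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("unexpected trailing input")
        return BELStatement(subject, relation, obj)


def parse_statement(text: str) -> BELStatement:
    """Parse a single-line BEL statement string.

    Whitespace-insensitive; identifiers may be quoted with single or double
    quotes (inner spaces preserved).  Raises :class:`BELParseError` naming the
    character offset on malformed input or nesting deeper than one function.
    """
    return _Parser(text).parse_statement()


def parse_term(text: str) -> BELTerm | BELComplex:
    """Parse a single BEL term (abundance, wrapped abundance, or complex)."""
    parser = _Parser(text)
    term = parser.parse_term()
    parser.skip_ws()
    if parser.pos != len(parser.text):
        raise parser.error("unexpected trailing input")
    return term


def _serialize_identifier(identifier: str) -> str:
    if identifier and all(c in _BARE_IDENT_CHARS for c in identifier):
        return identifier
    return '"' + identifier + '"'


def serialize_term(term: BELTerm | BELComplex) -> str:
    if isinstance(term, BELComplex):
        inner = ", ".join(serialize_term(m) for m in term.members)
        return f"complex({inner})"
    keyword = ABUNDANCE_KEYWORDS[term.entity_class]
    core = f"{keyword}({term.namespace}:{_serialize_identifier(term.identifier)})"
    if term.function_label != "none":
        return f"{term.function_label}({core})"
    return core


def serialize_statement(s: BELStatement) -> str:
    """Emit the canonical surface form ``TERM relation TERM``."""
    return f"{serialize_term(s.subject)} {s.relation} {serialize_term(s.object)}"


def canonicalize_relation(relation: str) -> str:
    return _RELATION_MAP[relation]


def canonicalize_function(label: str, activity_family: frozenset[str] = ACTIVITY_FAMILY) -> str:
    return "act" if label in activity_family else label


def _canonicalize_term(
    term: BELTerm | BELComplex, activity_family: frozenset[str]
) -> BELTerm | BELComplex:
    if isinstance(term, BELComplex):
        return term
    return replace(term, function_label=canonicalize_function(term.function_label, activity_family))


def canonicalize(
    s: BELStatement, activity_family: frozenset[str] = ACTIVITY_FAMILY
) -> BELStatement:
    """Fold the statement onto the classifier label space.

    ``directlyIncreases``/``directlyDecreases`` map to their indirect
    counterparts and any activity-family function maps to ``act``.
    Idempotent.
    """
    return BELStatement(
        _canonicalize_term(s.subject, activity_family),
        canonicalize_relation(s.relation),
        _canonicalize_term(s.object, activity_family),
    )
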