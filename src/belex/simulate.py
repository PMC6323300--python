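"""Seeded generator of synthetic BEL-annotated corpora.

The generator emulates the statistical shape of a causal-statement corpus:
2–5 entities per sentence (mostly genes/proteins), binary increases/decreases
relations cued by disjoint lexical trigger sets (active voice: ``elevates``
vs ``suppresses`` classes; passive voice reverses the argument order), unary
entity functions cued by context words placed within three tokens of the
wrapped entity (``degradation`` -> deg, ``phosphorylation`` -> pmod, ...),
multiple statements per sentence, and the label imbalance seen in curated
data (~72% of relations are increases; ~65% of non-none functions are act).

With ``cue_noise = 0`` the cue -> label mapping is deterministic and every
cue falls inside the 15-token function-detection window of its entity, so
the Bayes-optimal error of both classifiers is zero by construction.  The
synthetic namespace ``SYN`` with integer identifiers avoids any claim about
real gene symbols; the emitted lexicon doubles as input for dictionary-search
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bel import BELStatement, BELTerm, canonicalize
from .corpus import AnnotatedSentence, EntityMention, write_corpus, write_lexicon

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "generate",
    "describe",
    "RELATION_CUES",
    "FUNCTION_CUES",
]

RELATION_CUES = {
    ("increases", "active"): ("elevates", "augments", "upregulates", "induces", "stimulates"),
    ("increases", "passive"): ("elevated", "augmented", "upregulated", "induced", "stimulated"),
    ("decreases", "active"): ("suppresses", "inhibits", "reduces", "downregulates", "attenuates"),
    ("decreases", "passive"): ("suppressed", "inhibited", "reduced", "downregulated", "attenuated"),
}

FUNCTION_CUES = {
    "act": ("activity", "activation"),
    "deg": ("degradation", "proteolysis"),
    "pmod": ("phosphorylation", "methylation"),
    "sec": ("secretion", "exocytosis"),
}

FILLERS = (
    "levels", "expression", "signaling", "abundance", "turnover",
    "localization", "binding", "responses",
)

_SURFACE_PREFIX = {
    "gene_protein": "GP",
    "chemical": "CH",
    "disease": "DZ",
    "bioprocess": "BPR",
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults are the emulated study shape."""

    n_sentences: int = 100
    entities_per_sentence: dict[int, float] = field(
        default_factory=lambda: {2: 0.45, 3: 0.30, 4: 0.15, 5: 0.10}
    )
    p_relation: float = 0.75
    relation_mix: dict[str, float] = field(
        default_factory=lambda: {"increases": 0.72, "decreases": 0.28}
    )
    function_mix: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.58,
            "act": 0.273,
            "pmod": 0.080,
            "deg": 0.033,
            "sec": 0.034,
        }
    )
    entity_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "gene_protein": 0.85,
            "bioprocess": 0.09,
            "chemical": 0.04,
            "disease": 0.02,
        }
    )
    cue_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p_relation", "cue_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("entities_per_sentence", "relation_mix", "function_mix", "entity_class_mix"):
            mix = getattr(self, name)
            if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability distribution summing to 1")
        if not set(self.entities_per_sentence) <= {2, 3, 4, 5}:
            raise ValueError("entities_per_sentence supports 2-5 entities")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "entities_per_sentence" in d:
            d["entities_per_sentence"] = {int(k): v for k, v in d["entities_per_sentence"].items()}
        return cls(**d)


def _choice(rng: np.random.Generator, items, probs=None):
    idx = rng.choice(len(items), p=probs)
    return items[int(idx)]


class _SentenceBuilder:
    def __init__(self):
        self.tokens: list[str] = []
        self.mention_spans: dict[str, tuple[int, int]] = {}

    def word(self, token: str):
        self.tokens.append(token)

    def entity(self, surface: str, ns_id: str):
        self.mention_spans[ns_id] = (len(self.tokens), len(self.tokens) + 1)
        self.tokens.append(surface)


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedSentence], dict[str, list[str]]]:
    """Build the synthetic sentences and the accompanying synonym lexicon."""
    rng = np.random.default_rng(config.seed)
    n_choices = sorted(config.entities_per_sentence)
    n_probs = [config.entities_per_sentence[k] for k in n_choices]
    rel_labels = sorted(config.relation_mix)
    rel_probs = [config.relation_mix[k] for k in rel_labels]
    fun_labels = sorted(config.function_mix)
    fun_probs = [config.function_mix[k] for k in fun_labels]
    cls_labels = sorted(config.entity_class_mix)
    cls_probs = [config.entity_class_mix[k] for k in cls_labels]

    lexicon: dict[str, list[str]] = {}
    sentences: list[AnnotatedSentence] = []
    next_id = 1
    for s_idx in range(config.n_sentences):
        n = int(_choice(rng, n_choices, n_probs))
        entities = []  # (ns_id, surface, entity_class)
        for _ in range(n):
            entity_class = _choice(rng, cls_labels, cls_probs)
            ns_id = f"SYN:{next_id}"
            surface = f"{_SURFACE_PREFIX[entity_class]}{next_id}"
            lexicon[ns_id] = [surface, surface.lower()]
            entities.append((ns_id, surface, entity_class))
            next_id += 1
        order = rng.permutation(n)
        pairs = [(int(order[2 * k]), int(order[2 * k + 1])) for k in range(n // 2)]
        leftover = [int(order[-1])] if n % 2 else []

        builder = _SentenceBuilder()
        statements: list[BELStatement] = []
        if rng.random() < 0.5:
            builder.word("notably")
        first_clause = True
        for a, b in pairs:
            if not first_clause:
                builder.word(str(_choice(rng, ("and", "while", "whereas"))))
            first_clause = False
            if rng.random() < config.p_relation:
                relation = str(_choice(rng, rel_labels, rel_probs))
                voice = "active" if rng.random() < 0.5 else "passive"
                funcs = [str(_choice(rng, fun_labels, fun_probs)) for _ in range(2)]
                subj, obj = entities[a], entities[b]
                if voice == "active":
                    _entity_block(builder, subj, funcs[0], rng, config.cue_noise)
                    _cue(builder, RELATION_CUES[(relation, "active")], rng, config.cue_noise)
                    _entity_block(builder, obj, funcs[1], rng, config.cue_noise)
                else:
                    _entity_block(builder, obj, funcs[1], rng, config.cue_noise)
                    builder.word("is")
                    _cue(builder, RELATION_CUES[(relation, "passive")], rng, config.cue_noise)
                    builder.word("by")
                    _entity_block(builder, subj, funcs[0], rng, config.cue_noise)
                statements.append(
                    BELStatement(
                        BELTerm(subj[2], *subj[0].split(":", 1), funcs[0]),
                        relation,
                        BELTerm(obj[2], *obj[0].split(":", 1), funcs[1]),
                    )
                )
            else:
                e1, e2 = entities[a], entities[b]
                builder.entity(e1[1], e1[0])
                builder.word("and")
                builder.entity(e2[1], e2[0])
                builder.word("were")
                builder.word("detected")
        for k in leftover:
            if not first_clause:
                builder.word(str(_choice(rng, ("and", "while", "whereas"))))
            first_clause = False
            e = entities[k]
            builder.entity(e[1], e[0])
            builder.word(str(_choice(rng, FILLERS)))
            builder.word("were")
            builder.word("measured")

        mentions = sorted(
            (
                EntityMention(
                    start=span[0],
                    end=span[1],
                    surface=surface,
                    entity_class=entity_class,
                    ns_id=ns_id,
                )
                for ns_id, surface, entity_class in entities
                for span in (builder.mention_spans[ns_id],)
            ),
            key=lambda m: m.start,
        )
        sentences.append(
            AnnotatedSentence(
                sentence_id=f"S{s_idx:05d}",
                tokens=builder.tokens,
                mentions=mentions,
                gold_statements=statements,
                text=" ".join(builder.tokens),
            )
        )
    return sentences, lexicon


def _cue(builder: _SentenceBuilder, cues, rng, cue_noise: float):
    if rng.random() < cue_noise:
        builder.word(str(_choice(rng, FILLERS)))
    else:
        builder.word(str(_choice(rng, cues)))


def _entity_block(builder, entity, function_label: str, rng, cue_noise: float):
    ns_id, surface, _cls = entity
    if function_label == "none":
        builder.entity(surface, ns_id)
        return
    cues = FUNCTION_CUES[function_label]
    if rng.random() < 0.5:
        builder.entity(surface, ns_id)
        _cue(builder, cues, rng, cue_noise)
    else:
        _cue(builder, cues, rng, cue_noise)
        builder.word("of")
        builder.entity(surface, ns_id)


def generate(
    config: GeneratorConfig, corpus_path: str | Path, lexicon_path: str | Path
) -> tuple[Path, Path]:
    """Write the corpus (JSON-lines) and lexicon (TSV) files; deterministic
    given config and seed (same inputs -> byte-identical outputs)."""
    sentences, lexicon = generate_corpus(config)
    corpus_path, lexicon_path = Path(corpus_path), Path(lexicon_path)
    write_corpus(sentences, corpus_path)
    write_lexicon(lexicon, lexicon_path)
    return corpus_path, lexicon_path


def describe(sentences: list[AnnotatedSentence]) -> dict:
    """Corpus statistics: sentences, statements, entities by class,
    relations by canonical label, functions by canonical label."""
    stats = {
        "sentences": len(sentences),
        "statements": 0,
        "entities": {},
        "relations": {},
        "functions": {},
    }
    for s in sentences:
        stats["statements"] += len(s.gold_statements)
        for m in s.mentions:
            stats["entities"][m.entity_class] = stats["entities"].get(m.entity_class, 0) + 1
        for st in s.gold_statements:
            cst = canonicalize(st)
            stats["relations"][cst.relation] = stats["relations"].get(cst.relation, 0) + 1
            for side in (cst.subject, cst.object):
                if isinstance(side, BELTerm) and side.function_label != "none":
                    stats["functions"][side.function_label] = (
                        stats["functions"].get(side.function_label, 0) + 1
                    )
    return stats
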