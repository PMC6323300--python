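"""End-to-end orchestration: instance construction, RE and FD prediction,
threshold filtering and BEL statement merging.

Argument order: the relation classifier is trained on directional labels
(``increases>``, ``increases<``, ``decreases>``, ``decreases<``, ``none``)
where ``>`` means the left-hand mention of the pair is the statement subject.
Externally the labels collapse back to ``increases``/``decreases`` plus the
subject/object order, so a merged statement knows which entity is which.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

from .bel import BELStatement, BELTerm, canonicalize, serialize_statement
from .corpus import (
    AnnotatedSentence,
    FunctionInstance,
    RelationInstance,
    anonymize,
    build_function_instances,
    build_relation_instances,
)
from .model import AttBiLSTM, threshold_filter

__all__ = [
    "RELATION_LABELS",
    "directional_label",
    "collapse_directional",
    "prepare_relation_training",
    "prepare_function_training",
    "train_re",
    "train_fd",
    "mention_table",
    "merge",
    "run_pipeline",
    "write_predictions",
    "read_predictions",
]

RELATION_LABELS = ("none", "increases>", "increases<", "decreases>", "decreases<")


class PipelineError(RuntimeError):
    pass


def directional_label(inst: RelationInstance) -> str:
    """Directional training label for a relation instance."""
    if inst.label == "none":
        return "none"
    if inst.subject_first is None:
        raise ValueError("labeled relation instance lacks argument order")
    return inst.label + (">" if inst.subject_first else "<")


def collapse_directional(label: str) -> tuple[str, bool | None]:
    """Directional label -> (canonical relation, subject_first)."""
    if label == "none":
        return "none", None
    return label[:-1], label[-1] == ">"


def prepare_relation_training(sentences) -> list[RelationInstance]:
    instances = []
    for s in sentences:
        for inst in build_relation_instances(anonymize(s), mode="train"):
            inst.train_label = directional_label(inst)
            instances.append(inst)
    return instances


def prepare_function_training(sentences) -> list[FunctionInstance]:
    instances = []
    for s in sentences:
        instances.extend(build_function_instances(anonymize(s), mode="train"))
    return instances


def train_re(sentences, config) -> AttBiLSTM:
    """Train the relation-extraction model (directional label set)."""
    config = copy.deepcopy(config)
    config.num_positions = 2
    config.label_set = RELATION_LABELS
    return AttBiLSTM(config).fit(prepare_relation_training(sentences))


def train_fd(sentences, config) -> AttBiLSTM:
    """Train the function-detection model."""
    from .bel import FD_LABELS

    config = copy.deepcopy(config)
    config.num_positions = 1
    config.label_set = FD_LABELS
    return AttBiLSTM(config).fit(prepare_function_training(sentences))


def mention_table(sentence: AnnotatedSentence) -> dict[str, tuple[str, str]]:
    """placeholder -> (entity_class, ns_id) for an anonymized sentence."""
    table = {}
    for m in sentence.mentions:
        if m.placeholder is None:
            raise ValueError("sentence must be anonymized first")
        table[m.placeholder] = (m.entity_class, m.ns_id)
    return table


def _term(placeholder: str, table: dict, function_label: str) -> BELTerm:
    if placeholder not in table:
        raise PipelineError(f"placeholder {placeholder!r} missing from mention table")
    entity_class, ns_id = table[placeholder]
    namespace, identifier = ns_id.split(":", 1)
    return BELTerm(entity_class, namespace, identifier, function_label)


def merge(
    relation_predictions: list[RelationInstance],
    function_predictions: list[FunctionInstance],
    mention_tables: dict[str, dict[str, tuple[str, str]]],
) -> dict[str, list[BELStatement]]:
    """Combine predicted relations with (already filtered) predicted functions
    into canonical BEL statements, deduplicated per sentence.

    Every relation instance with a non-``none`` label yields one statement:
    placeholders are recovered to namespace identifiers through the mention
    table, each term is wrapped by its predicted function when not ``none``,
    and subject/object order follows the directional relation label.
    """
    fd_label: dict[tuple[str, str], str] = {}
    for inst in function_predictions:
        fd_label[(inst.sentence_id, inst.placeholder)] = inst.label

    out: dict[str, list[BELStatement]] = {sid: [] for sid in mention_tables}
    for inst in relation_predictions:
        sid = inst.sentence_id
        if sid not in out:
            out[sid] = []
        relation, subject_first = collapse_directional(inst.label)
        if relation == "none":
            continue
        if subject_first is None:
            subject_first = inst.subject_first if inst.subject_first is not None else True
        table = mention_tables.get(sid)
        if table is None:
            raise PipelineError(f"no mention table for sentence {sid!r}")
        subj_ph, obj_ph = (
            (inst.e1_placeholder, inst.e2_placeholder)
            if subject_first
            else (inst.e2_placeholder, inst.e1_placeholder)
        )
        subject = _term(subj_ph, table, fd_label.get((sid, subj_ph), "none"))
        obj = _term(obj_ph, table, fd_label.get((sid, obj_ph), "none"))
        statement = canonicalize(BELStatement(subject, relation, obj))
        if statement not in out[sid]:
            out[sid].append(statement)
    return out


def run_pipeline(
    sentences: list[AnnotatedSentence],
    re_model: AttBiLSTM,
    fd_model: AttBiLSTM,
    tau: float = 0.8,
    out_path: str | Path | None = None,
) -> dict[str, list[BELStatement]]:
    """Anonymize, build test instances, predict, filter and merge.

    Returns predicted canonical statements per sentence id; optionally writes
    them as JSON-lines (``{"id": ..., "statements": [...]}``).
    Deterministic given the trained models.
    """
    anonymized = [anonymize(s) for s in sentences]
    tables = {s.sentence_id: mention_table(s) for s in anonymized}
    re_instances = []
    fd_instances = []
    for s in anonymized:
        re_instances.extend(build_relation_instances(s, mode="test"))
        fd_instances.extend(build_function_instances(s, mode="test"))
    re_model.predict(re_instances)
    fd_model.predict(fd_instances)
    threshold_filter(fd_instances, tau)
    predictions = merge(re_instances, fd_instances, tables)
    if out_path is not None:
        write_predictions(predictions, out_path)
    return predictions


def write_predictions(predictions: dict[str, list[BELStatement]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in predictions:
            rec = {"id": sid, "statements": [serialize_statement(s) for s in predictions[sid]]}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_predictions(path: str | Path) -> dict[str, list[BELStatement]]:
    from .bel import parse_statement

    out: dict[str, list[BELStatement]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out[str(rec["id"])] = [parse_statement(t) for t in rec["statements"]]
    return out
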