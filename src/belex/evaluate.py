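"""Six-level precision/recall/F1 scorer for predicted vs gold BEL statements.

Both sides are canonicalized first, then per-sentence comparable units are
extracted at each level:

* ``T`` (Term) — bare entity terms ``namespace:identifier`` (two per binary
  statement);
* ``Fun`` (Function) — (function, term) units for functions other than
  ``none``, matched on both components;
* ``FS`` (Function-Secondary) — the same units with partial credit: a match
  requires only the term, not the function label;
* ``Rel`` (Relation) — function-stripped ordered triples (subject term,
  relation, object term);
* ``RS`` (Relation-Secondary) — triples matched when at least two of the
  three components agree;
* ``Stat`` (Statement) — full canonical statements including function
  wrappers.

Units are multiset-matched one-to-one within each sentence.  For the exact
levels this is multiset intersection; for the partial-credit levels (FS, RS)
a maximum bipartite matching is computed so the reported counts are the best
achievable pairing.  Corpus scores are micro-averaged over sentences and
reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .bel import BELComplex, BELStatement, BELTerm, canonicalize, serialize_statement

__all__ = ["LEVELS", "LevelScore", "EvalReport", "score", "sweep_tau", "micro_f1"]

LEVELS = ("T", "FS", "Fun", "RS", "Rel", "Stat")


@dataclass
class LevelScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    levels: dict[str, LevelScore]

    def __getitem__(self, level: str) -> LevelScore:
        return self.levels[level]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": lv,
                "tp": sc.tp,
                "fp": sc.fp,
                "fn": sc.fn,
                "P": round(sc.precision, 1),
                "R": round(sc.recall, 1),
                "F1": round(sc.f1, 1),
            }
            for lv, sc in self.levels.items()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _term_key(t: BELTerm) -> str:
    return t.ns_id


def _sides(s: BELStatement):
    for side in (s.subject, s.object):
        if isinstance(side, BELComplex):
            yield from side.members
        else:
            yield side


def _units(statements: list[BELStatement], level: str) -> list:
    units = []
    for s in statements:
        if level == "T":
            units.extend(_term_key(t) for t in _sides(s))
        elif level in ("Fun", "FS"):
            units.extend(
                (t.function_label, _term_key(t))
                for t in _sides(s)
                if t.function_label != "none"
            )
        elif level in ("Rel", "RS"):
            if isinstance(s.subject, BELTerm) and isinstance(s.object, BELTerm):
                units.append((_term_key(s.subject), s.relation, _term_key(s.object)))
        elif level == "Stat":
            units.append(serialize_statement(s))
        else:
            raise ValueError(f"unknown level {level!r}")
    return units


def _match_predicate(level: str, pred, gold) -> bool:
    if level == "FS":
        return pred[1] == gold[1]  # term must match, function label free
    if level == "RS":
        return sum(p == g for p, g in zip(pred, gold)) >= 2
    return pred == gold


def _count_matches(pred_units: list, gold_units: list, level: str) -> int:
    """One-to-one matches between the two unit multisets.

    Exact levels use multiset intersection; partial levels use a maximum
    bipartite matching (optimal assignment), with full-equality pairs
    preferred among equally sized matchings.
    """
    if not pred_units or not gold_units:
        return 0
    if level not in ("FS", "RS"):
        matched = 0
        remaining = list(gold_units)
        for unit in pred_units:
            if unit in remaining:
                remaining.remove(unit)
                matched += 1
        return matched
    weight = np.zeros((len(pred_units), len(gold_units)))
    for i, p in enumerate(pred_units):
        for j, g in enumerate(gold_units):
            if _match_predicate(level, p, g):
                # tiny bonus keeps exact pairs together without changing the
                # matched count
                weight[i, j] = 1.0 + (1e-6 if p == g else 0.0)
    rows, cols = linear_sum_assignment(-weight)
    return int(sum(weight[r, c] >= 1.0 for r, c in zip(rows, cols)))


def score(
    gold: dict[str, list[BELStatement]], predicted: dict[str, list[BELStatement]]
) -> EvalReport:
    """Micro-averaged six-level scores of predicted against gold statements.

    Both inputs map sentence id -> statements and must cover the same
    sentence ids.  Statements are canonicalized before unit extraction.
    """
    if set(gold) != set(predicted):
        missing = set(gold) ^ set(predicted)
        raise ValueError(f"sentence-id mismatch between gold and predictions: {sorted(missing)[:5]}")
    report = {lv: LevelScore() for lv in LEVELS}
    for sid in gold:
        g_stmts = [canonicalize(s) for s in gold[sid]]
        p_stmts = [canonicalize(s) for s in predicted[sid]]
        for lv in LEVELS:
            g_units = _units(g_stmts, lv)
            p_units = _units(p_stmts, lv)
            tp = _count_matches(p_units, g_units, lv)
            report[lv].tp += tp
            report[lv].fp += len(p_units) - tp
            report[lv].fn += len(g_units) - tp
    return EvalReport(report)


def micro_f1(gold_labels, predicted_labels) -> float:
    """Micro-averaged F1 over single-label instances (equals accuracy)."""
    gold_labels = list(gold_labels)
    predicted_labels = list(predicted_labels)
    if len(gold_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    if not gold_labels:
        return 0.0
    return sum(g == p for g, p in zip(gold_labels, predicted_labels)) / len(gold_labels)


def sweep_tau(
    gold: dict[str, list[BELStatement]],
    relation_predictions,
    function_predictions,
    mention_tables,
    taus,
) -> tuple[pd.DataFrame, float]:
    """Statement-level F1 as a function of the filtering threshold.

    Re-applies threshold filtering, merging and scoring for each tau on
    cached unfiltered predictions; returns the grid as a table and the
    argmax tau (first on ties).
    """
    import copy

    from .model import threshold_filter
    from .pipeline import merge

    rows = []
    for tau in taus:
        fd = copy.deepcopy(function_predictions)
        threshold_filter(fd, tau)
        predictions = merge(relation_predictions, fd, mention_tables)
        report = score(gold, predictions)
        rows.append(
            {
                "tau": float(tau),
                "stat_f1": report["Stat"].f1,
                "fun_f1": report["Fun"].f1,
                "retained_functions": sum(1 for inst in fd if inst.label != "none"),
            }
        )
    table = pd.DataFrame(rows)
    best_tau = float(table.loc[table["stat_f1"].idxmax(), "tau"])
    return table, best_tau
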