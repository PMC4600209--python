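"""Contact Assessment Rehabilitation Algorithm (RA) scorer.

The RA is an expert-derived decision tree over Contact Assessment (CA)
items that assigns each potential home-care client a priority score from 1
to 5; higher scores flag clients more likely to need rehabilitation.  Its
published ingredients are a recent decline in ability to perform activities
of daily living (D5), functional/mobility items (D4A-D4D) and the binary
Self-Reliance indicator:

    impaired  iff  C1 = 1  (modified-independent or any impairment in
                            cognitive skills for daily decision making)
              or any of C2A (bathing), C2B (personal hygiene),
              C2C (dressing lower body), C2D (locomotion) = 1.

The Self-Reliance rule is hard-coded; the split structure of the tree is
configuration-driven because the licensed algorithm's exact splits live in
the CA user's manual.  The packaged :data:`DEFAULT_TREE` is a synthetic,
non-canonical stand-in built from the published ingredients — it must not be
presented as the licensed algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .data_model import ValidationError

IMPAIRED = "impaired"
INTACT = "intact"

SELF_RELIANCE_ITEMS = ("C1", "C2A", "C2B", "C2C", "C2D")


class ScoringError(ValueError):
    """A record could not be scored against the configured tree."""


def self_reliance(record: Mapping) -> str:
    """Binary Self-Reliance indicator: ``"impaired"`` iff any of C1,
    C2A-C2D equals 1; all five fields must be present and binary."""
    flags = []
    for code in SELF_RELIANCE_ITEMS:
        if code not in record:
            raise ScoringError(f"self-reliance item {code!r} is missing")
        v = record[code]
        if v not in (0, 1):
            raise ScoringError(f"self-reliance item {code!r} must be 0/1, got {v!r}")
        flags.append(int(v))
    return IMPAIRED if any(flags) else INTACT


# ---------------------------------------------------------------------------
# Configurable decision tree
# ---------------------------------------------------------------------------

_OPS = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    "in": lambda a, b: a in b,
}

_PREDICATES = {"self_reliance": self_reliance}


def validate_tree(node: Mapping, _depth: int = 0) -> None:
    """Check a tree config: finite, every path ends in a leaf with score 1-5."""
    if _depth > 64:
        raise ValidationError("tree deeper than 64 levels; refusing")
    if not isinstance(node, Mapping):
        raise ValidationError(f"tree node must be a mapping, got {type(node).__name__}")
    if "score" in node:
        if node["score"] not in (1, 2, 3, 4, 5):
            raise ValidationError(f"leaf score {node['score']!r} outside 1..5")
        return
    if "predicate" in node:
        if node["predicate"] not in _PREDICATES:
            raise ValidationError(f"unknown predicate {node['predicate']!r}")
    elif "item" in node:
        if node.get("op", ">=") not in _OPS:
            raise ValidationError(f"unknown operator {node.get('op')!r}")
        if "value" not in node:
            raise ValidationError(f"node on item {node['item']!r} lacks a threshold value")
    else:
        raise ValidationError("node is neither a leaf, an item test nor a predicate")
    for branch in ("if_true", "if_false"):
        if branch not in node:
            raise ValidationError(f"decision node missing {branch!r} child")
        validate_tree(node[branch], _depth + 1)


def ra_score(record: Mapping, tree: Mapping | None = None) -> int:
    """Deterministically traverse the tree for one record; returns 1..5.

    Derived predicates (self-reliance) are evaluated on demand.  A record
    missing an item referenced by the current node raises
    :class:`ScoringError` naming the node.
    """
    node = DEFAULT_TREE if tree is None else tree
    while True:
        if "score" in node:
            return int(node["score"])
        if "predicate" in node:
            value = _PREDICATES[node["predicate"]](record)
            branch = value == node.get("equals", IMPAIRED)
        else:
            code = node["item"]
            if code not in record:
                raise ScoringError(f"record missing item {code!r} required by tree node")
            branch = _OPS[node.get("op", ">=")](record[code], node["value"])
        node = node["if_true"] if branch else node["if_false"]


def score_frame(df: pd.DataFrame, tree: Mapping | None = None) -> pd.Series:
    """Score every row of a CA-item table."""
    tree = DEFAULT_TREE if tree is None else tree
    validate_tree(tree)
    return pd.Series(
        [ra_score(row, tree) for row in df.to_dict("records")],
        index=df.index, name="ra_score",
    )


def load_tree(path) -> dict:
    with open(path) as fh:
        tree = yaml.safe_load(fh)
    validate_tree(tree)
    return tree


# Synthetic stand-in tree (NOT the licensed algorithm): built only from the
# published ingredients — ADL decline (D5) at the root, Self-Reliance, and
# the functional/mobility items D4B/D4D.  Every score 1..5 is reachable.
DEFAULT_TREE: dict = {
    "item": "D5", "op": ">=", "value": 1,
    "if_true": {
        "predicate": "self_reliance", "equals": IMPAIRED,
        "if_true": {
            "item": "D4D", "op": ">=", "value": 1,
            "if_true": {"score": 5},
            "if_false": {"score": 4},
        },
        "if_false": {
            "item": "D4D", "op": ">=", "value": 1,
            "if_true": {"score": 4},
            "if_false": {"score": 3},
        },
    },
    "if_false": {
        "predicate": "self_reliance", "equals": IMPAIRED,
        "if_true": {
            "item": "D4B", "op": ">=", "value": 1,
            "if_true": {"score": 3},
            "if_false": {"score": 2},
        },
        "if_false": {
            "item": "D4D", "op": ">=", "value": 1,
            "if_true": {"score": 2},
            "if_false": {"score": 1},
        },
    },
}


# ---------------------------------------------------------------------------
# Overlap between data-driven top items and the RA's expert item list
# ---------------------------------------------------------------------------

# Published comparison inputs: the home-care items top-ranked by both
# rankers on the real data, the CA items inside the RA, and the crosswalk
# between instruments where equivalents exist.
TOP_HC_ITEMS: tuple[str, ...] = (
    "K6A", "H3", "K6B", "J1X", "H7A", "K5", "P2W", "H4B", "H5", "H4A", "O2B",
)
RA_CA_ITEMS: tuple[str, ...] = (
    "D5", "D4D", "D4A", "D4B", "D4C", "C1", "C2A", "C2B", "C2C", "C2D",
)
HC_CA_CROSSWALK: dict[str, str] = {"H3": "D5", "H5": "D4D"}
ITEM_LABELS: dict[str, str] = {
    "K6A": "Unsteady gait",
    "H3": "ADL decline",
    "K6B": "Limits going outdoors due to fear of falling",
    "J1X": "Cancer (last 5 years)",
    "H7A": "Client believes can improve",
    "K5": "Falls frequency",
    "P2W": "Nurse monitoring < daily",
    "H4B": "Mode of locomotion - outdoors",
    "H5": "Stair climbing",
    "H4A": "Mode of locomotion - indoors",
    "O2B": "Better off in different environment",
    "D5": "ADL decline",
    "D4D": "Stair climbing",
    "D4A": "Meal preparation",
    "D4B": "Managing housework",
    "D4C": "Managing medications",
    "C1": "Skills of daily decision making",
    "C2A": "Bathing",
    "C2B": "Personal hygiene",
    "C2C": "Dressing lower body",
    "C2D": "Locomotion",
}


@dataclass
class OverlapReport:
    """Items shared between a data-driven top list and the RA item list."""

    overlap: list[tuple[str, str]]   # (hc_item, ca_item) pairs present on both sides
    hc_only: list[str]
    ca_only: list[str]

    @property
    def overlap_labels(self) -> set[str]:
        return {ITEM_LABELS.get(hc, hc) for hc, _ in self.overlap}


def items_overlap(top_ranked, ra_items: Iterable[str] = RA_CA_ITEMS,
                  crosswalk: Mapping[str, str] = HC_CA_CROSSWALK,
                  top_threshold: float = 20.0) -> OverlapReport:
    """Cross-instrument overlap between top-ranked items and the RA's list.

    ``top_ranked`` is either an explicit list of home-care item codes or a
    :class:`~rehabrank.ensemble.RankSummary` (items at mean rank <=
    ``top_threshold`` are taken).  An empty crosswalk yields an empty
    overlap with both lists reported fully.
    """
    if hasattr(top_ranked, "top"):
        hc_items = sorted(top_ranked.top(top_threshold))
    else:
        hc_items = list(top_ranked)
    ra_set = set(ra_items)
    overlap = [(hc, crosswalk[hc]) for hc in hc_items
               if hc in crosswalk and crosswalk[hc] in ra_set]
    matched_hc = {hc for hc, _ in overlap}
    matched_ca = {ca for _, ca in overlap}
    return OverlapReport(
        overlap=overlap,
        hc_only=[hc for hc in hc_items if hc not in matched_hc],
        ca_only=[ca for ca in ra_items if ca not in matched_ca],
    )
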