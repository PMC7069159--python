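"""Binary classification trees grown from projection-based feature rankings.

Each internal node carries one condition — presence/absence for a binary
code, ``value < threshold`` for a continuous feature such as age, with the
cut-off chosen by the highest information gain ratio.  Split features are
chosen per node from the star-coordinates LDA ranking: automatically (the
top-scored feature) or through an interactive callback that receives the
ranked score table and the node's projection, mirroring how a clinician
reads the plot and picks the longest vector pointing toward class
separation.  Growth stops when a node is pure enough, too small, too deep,
or has no usable feature left.

Trees serialize to JSON (round-trip identity) and export to Graphviz DOT
with the field's rendering conventions: per-node sample counts in square
brackets, leaf class with its percentage, node fill colored by predominant
class with darkness increasing with purity, the satisfied branch on the left.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import to_hex, to_rgb

from ._entropy import gain_ratio_threshold
from .cohort import CONTINUOUS, Cohort, FeatureSchema
from .projection import ProjectionModel, discriminative_scores, fit_lda_projection

__all__ = [
    "SplitCondition",
    "TreeNode",
    "ClassificationTree",
    "NodeStyle",
    "best_threshold",
    "split_node",
    "build_tree",
    "predict",
    "node_style",
    "serialize_tree",
    "deserialize_tree",
    "export_dot",
    "feature_level_table",
    "DEFAULT_CLASS_COLORS",
]

BINARY_PRESENCE = "binary_presence"
THRESHOLD = "threshold"

# palette used throughout: brown healthy, orange hypertension, purple
# diabetes, green both, blue both plus another dominant chronic disease
DEFAULT_CLASS_COLORS = {
    "CRG-1000": "#8c564b",
    "CRG-5192": "#ff7f0e",
    "CRG-5424": "#9467bd",
    "CRG-6144": "#2ca02c",
    "CRG-7071": "#1f77b4",
}
_FALLBACK_CYCLE = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                   "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


@dataclass(frozen=True)
class SplitCondition:
    """A node's decision rule: code presence, or value < threshold."""

    feature: str
    kind: str  # binary_presence | threshold
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (BINARY_PRESENCE, THRESHOLD):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind == THRESHOLD and self.threshold is None:
            raise ValueError("threshold condition needs a threshold value")

    def describe(self) -> str:
        if self.kind == BINARY_PRESENCE:
            return f"'{self.feature}' present"
        return f"{self.feature} < {self.threshold:g}"


@dataclass
class TreeNode:
    class_counts: dict
    level: int
    condition: SplitCondition | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None  # (satisfied, unsatisfied)
    projection: ProjectionModel | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())

    @property
    def predominant_class(self):
        # ties broken by class declaration order (dict order)
        best, best_n = None, -1
        for c, n in self.class_counts.items():
            if n > best_n:
                best, best_n = c, n
        return best

    @property
    def purity(self) -> float:
        total = self.n_samples
        return max(self.class_counts.values()) / total if total else 0.0


@dataclass
class ClassificationTree:
    root: TreeNode
    schema: FeatureSchema
    classes: list
    build_log: list = field(default_factory=list)

    def depth(self) -> int:
        def _d(node):
            if node.is_leaf:
                return node.level
            return max(_d(c) for c in node.children)
        return _d(self.root)

    def leaves(self) -> list[TreeNode]:
        out = []

        def _walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                for c in node.children:
                    _walk(c)
        _walk(self.root)
        return out


@dataclass(frozen=True)
class NodeStyle:
    hue: str  # class color hex, or "white"
    lightness: float
    fill: str  # resolved hex fill color


def best_threshold(values, labels) -> float:
    """Cut-off for a continuous feature by the highest information gain ratio.

    Candidates are midpoints between consecutive sorted distinct values; ties
    take the smallest threshold.  Raises ``ValueError`` when the column is
    constant or no candidate has positive gain (e.g. one class only).
    """
    t, ratio = gain_ratio_threshold(np.asarray(values, dtype=float), np.asarray(labels))
    if ratio <= 0.0:
        raise ValueError("no informative split: every candidate has zero gain")
    return t


def split_node(cohort: Cohort, condition: SplitCondition):
    """Partition a node's samples into (satisfied, unsatisfied) subsets."""
    if cohort.n_samples == 0:
        raise ValueError("cannot split an empty cohort")
    col = cohort.column(condition.feature)
    if condition.kind == BINARY_PRESENCE:
        if cohort.schema.kind_of(condition.feature) == CONTINUOUS:
            raise ValueError(f"presence split on continuous feature {condition.feature!r}")
        mask = col == 1.0
    else:
        if cohort.schema.kind_of(condition.feature) != CONTINUOUS:
            raise ValueError(f"threshold split on binary feature {condition.feature!r}")
        mask = col < condition.threshold
    return cohort.select_samples(mask), cohort.select_samples(~mask)


def _node_candidates(sub: Cohort, used_binary: set, ranking: list[str]):
    """Yield (feature, condition) for rank-ordered features usable at a node."""
    for name in ranking:
        kind = sub.schema.kind_of(name)
        col = sub.column(name)
        if kind == CONTINUOUS:
            try:
                t = best_threshold(col, sub.y)
            except ValueError:
                continue
            yield name, SplitCondition(name, THRESHOLD, t)
        else:
            if name in used_binary:
                continue
            if col.min() == col.max():  # constant: degenerate one-sided split
                continue
            yield name, SplitCondition(name, BINARY_PRESENCE)


def build_tree(
    cohort: Cohort,
    selector="auto",
    purity_stop: float = 0.9,
    min_node_size: int | None = None,
    max_depth: int = 14,
    ridge: float | None = None,
    store_projections: bool = False,
) -> ClassificationTree:
    """Grow a binary tree by projection-guided recursive splitting.

    At every impure node a local LDA projection is fitted (constant columns
    dropped), features are ranked by their discriminative score, and the
    split feature comes from ``selector``: ``"auto"`` takes the top-ranked
    usable feature; a callable receives a context dict with the ranked
    ``candidates``, the ``scores`` table, the ``projection`` model, the
    node's ``class_counts`` and ``level``, and returns a feature name.
    Binary features are split by presence and never reused on a path;
    continuous features split at their best gain-ratio cut-off and may recur
    with different thresholds.

    A node becomes a leaf when its purity reaches ``purity_stop``, it holds
    fewer than ``min_node_size`` samples (default max(10, 1% of the root)),
    its level reaches ``max_depth``, only one class remains, or no usable
    feature is left.  Leaf class = majority, ties by class order.
    """
    if len(cohort.classes) < 2:
        classes = cohort.classes
        root = TreeNode({c: int((cohort.y == c).sum()) for c in classes}, level=1)
        return ClassificationTree(root, cohort.schema, classes, [])
    if not 0 < purity_stop <= 1:
        raise ValueError("purity_stop must be in (0, 1]")
    if min_node_size is None:
        min_node_size = max(10, int(0.01 * cohort.n_samples))
    if min_node_size < 1 or max_depth < 1:
        raise ValueError("min_node_size and max_depth must be positive")

    classes = cohort.classes
    log: list[dict] = []
    interactive = callable(selector)

    def grow(sub: Cohort, level: int, used_binary: frozenset, path: str) -> TreeNode:
        counts = {c: int((sub.y == c).sum()) for c in classes}
        node = TreeNode(counts, level=level)
        present = sum(1 for v in counts.values() if v)
        if (present <= 1 or node.purity >= purity_stop
                or sub.n_samples < min_node_size or level >= max_depth):
            return node
        try:
            model = fit_lda_projection(sub.X, sub.y, schema=sub.schema, ridge=ridge)
            scores = discriminative_scores(model)
        except ValueError:
            return node  # degenerate node: constant features or inseparable classes
        candidates = list(_node_candidates(sub, used_binary, scores.ranking()))
        if not candidates:
            return node
        if store_projections:
            node.projection = model
        names = [f for f, _ in candidates]
        if interactive:
            chosen = selector({
                "level": level,
                "path": path,
                "class_counts": counts,
                "candidates": names,
                "scores": scores,
                "projection": model,
            })
            if chosen not in names:
                raise ValueError(f"selector returned {chosen!r}, not among candidates {names}")
        else:
            chosen = names[0]
        condition = dict(candidates)[chosen]
        log.append({
            "path": path,
            "level": level,
            "candidates": names[:10],
            "chosen": chosen,
            "condition": condition.describe(),
            "chooser": "interactive" if interactive else "auto",
        })
        sat, unsat = split_node(sub, condition)
        used = used_binary | ({chosen} if condition.kind == BINARY_PRESENCE else frozenset())
        node.condition = condition
        node.children = (
            grow(sat, level + 1, used, path + "L"),
            grow(unsat, level + 1, used, path + "R"),
        )
        return node

    root = grow(cohort, 1, frozenset(), "")
    if root.is_leaf and len(cohort.classes) >= 2 and cohort.n_samples >= min_node_size \
            and root.purity < purity_stop:
        raise ValueError("no splittable feature at the root")
    return ClassificationTree(root, cohort.schema, classes, log)


def _descend(tree: ClassificationTree, x: np.ndarray) -> TreeNode:
    node = tree.root
    while not node.is_leaf:
        cond = node.condition
        v = x[tree.schema.index_of(cond.feature)]
        satisfied = (v == 1.0) if cond.kind == BINARY_PRESENCE else (v < cond.threshold)
        node = node.children[0] if satisfied else node.children[1]
    return node


def predict(tree: ClassificationTree, sample) -> object:
    """Classify one sample (or each row of a matrix) by top-down descent."""
    x = np.asarray(sample, dtype=float)
    if x.ndim == 1:
        if x.shape[0] != tree.schema.n:
            raise ValueError(f"expected {tree.schema.n} features, got {x.shape[0]}")
        return _descend(tree, x).predominant_class
    return np.array([_descend(tree, row).predominant_class for row in x])


def node_style(node: TreeNode, predominance_threshold: float = 0.5,
               class_colors: dict | None = None) -> NodeStyle:
    """Fill style of a node: class hue, darkness increasing with purity.

    Nodes without a clearly predominant class (purity below the threshold)
    are white.  Otherwise purity maps linearly from
    [threshold, 1] onto lightness [0.85, 0.35] in HLS space around the
    class's hue, so a pure node is darkest.
    """
    if not node.class_counts or node.n_samples == 0:
        raise ValueError("empty node has no style")
    purity = node.purity
    if purity < predominance_threshold:
        return NodeStyle(hue="white", lightness=1.0, fill="#ffffff")
    colors = {**DEFAULT_CLASS_COLORS, **(class_colors or {})}
    cls = node.predominant_class
    base = colors.get(cls)
    if base is None:
        idx = list(node.class_counts).index(cls)
        base = _FALLBACK_CYCLE[idx % len(_FALLBACK_CYCLE)]
    frac = (purity - predominance_threshold) / (1.0 - predominance_threshold) \
        if predominance_threshold < 1 else 1.0
    light = 0.85 - 0.5 * frac
    h, _, s = colorsys.rgb_to_hls(*to_rgb(base))
    fill = to_hex(colorsys.hls_to_rgb(h, light, s))
    return NodeStyle(hue=base, lightness=light, fill=fill)


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "condition": None if node.condition is None else {
            "feature": node.condition.feature,
            "kind": node.condition.kind,
            "threshold": node.condition.threshold,
        },
        "counts": {str(c): int(v) for c, v in node.class_counts.items()},
        "level": node.level,
        "children": None if node.is_leaf else [_node_to_dict(c) for c in node.children],
    }
    return d


def _node_from_dict(d: dict) -> TreeNode:
    cond = None
    if d["condition"] is not None:
        c = d["condition"]
        cond = SplitCondition(c["feature"], c["kind"], c["threshold"])
    children = None
    if d["children"] is not None:
        children = tuple(_node_from_dict(x) for x in d["children"])
    return TreeNode(dict(d["counts"]), level=d["level"], condition=cond, children=children)


def serialize_tree(tree: ClassificationTree) -> str:
    """Serialize to JSON: nested nodes with condition, counts, children, level."""
    return json.dumps(
        {
            "classes": [str(c) for c in tree.classes],
            "schema": [
                {"name": f.name, "kind": f.kind, "system": f.system}
                for f in tree.schema.features
            ],
            "root": _node_to_dict(tree.root),
            "build_log": tree.build_log,
        },
        indent=2,
        sort_keys=True,
    )


def deserialize_tree(text: str) -> ClassificationTree:
    from .cohort import Feature  # local import to keep module tops light

    d = json.loads(text)
    schema = FeatureSchema(tuple(Feature(f["name"], f["kind"], f["system"]) for f in d["schema"]))
    return ClassificationTree(_node_from_dict(d["root"]), schema, list(d["classes"]),
                              d.get("build_log", []))


def export_dot(tree: ClassificationTree, predominance_threshold: float = 0.5,
               class_colors: dict | None = None) -> str:
    """Graphviz DOT text for a tree.

    Internal nodes show the decision rule, the sample total and per-class
    counts in square brackets; leaves show the predominant class with the
    percentage of the node's samples belonging to it (in brackets).  The
    satisfied branch is drawn first (left).
    """
    lines = [
        "digraph ClassificationTree {",
        '  graph [ordering=out];',
        '  node [shape=box, style="filled,rounded", fontname="Helvetica"];',
    ]
    counter = [0]

    def emit(node: TreeNode) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        counts = "[" + ", ".join(str(node.class_counts[c]) for c in tree.classes) + "]"
        style = node_style(node, predominance_threshold, class_colors)
        if node.is_leaf:
            pct = 100.0 * node.purity
            label = f"{node.predominant_class} ({pct:.1f}%)\\nn={node.n_samples} {counts}"
        else:
            label = f"{node.condition.describe()}\\nn={node.n_samples} {counts}"
        lines.append(f'  {nid} [label="{label}", fillcolor="{style.fill}"];')
        if not node.is_leaf:
            sat = emit(node.children[0])
            unsat = emit(node.children[1])
            lines.append(f'  {nid} -> {sat} [label="yes"];')
            lines.append(f'  {nid} -> {unsat} [label="no"];')
        return nid

    emit(tree.root)
    lines.append("}")
    return "\n".join(lines) + "\n"


def feature_level_table(trees: dict) -> pd.DataFrame:
    """Levels at which each feature is tested, per tree (root = level 1).

    Returns a DataFrame indexed by feature with one column per tree; each
    cell is the sorted tuple of levels of internal nodes testing that
    feature, or an empty tuple when the tree never uses it.
    """
    usage: dict[str, dict[str, set]] = {}

    def walk(node: TreeNode, name: str):
        if node.is_leaf:
            return
        usage.setdefault(node.condition.feature, {}).setdefault(name, set()).add(node.level)
        for c in node.children:
            walk(c, name)

    for name, tree in trees.items():
        walk(tree.root, name)
    rows = {}
    for feat in sorted(usage):
        rows[feat] = {name: tuple(sorted(usage[feat].get(name, ()))) for name in trees}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(trees))
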