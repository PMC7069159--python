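"""Threshold search, splitting, guided tree construction, styling, export."""

import json

import numpy as np
import pytest

from sctree.cohort import Cohort
from sctree.synthetic import generate_cohort, structured_demo_spec
from sctree.tree import (BINARY_PRESENCE, THRESHOLD, SplitCondition, TreeNode,
                         best_threshold, build_tree, deserialize_tree,
                         export_dot, feature_level_table, node_style, predict,
                         serialize_tree, split_node)
from sctree._entropy import entropy_bits

from conftest import make_schema, marker_spec


# ---------------------------------------------------------------- thresholds

def exhaustive_best_threshold(values, labels):
    """Independent oracle: evaluate the gain ratio at every midpoint."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    distinct = np.sort(np.unique(values))
    n = len(labels)
    h = entropy_bits(labels)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2
        m = values < t
        p = m.sum() / n
        si = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        gain = h - (p * entropy_bits(labels[m]) + (1 - p) * entropy_bits(labels[~m]))
        ratio = gain / si
        if best is None or ratio > best[1] + 1e-12:
            best = (t, ratio)
    return best


def test_best_threshold_worked_examples():
    assert best_threshold([20, 25, 35, 40], ["A", "A", "B", "B"]) == 30.0
    assert best_threshold([1, 2], ["A", "B"]) == 1.5


def test_best_threshold_degenerate_inputs():
    with pytest.raises(ValueError):
        best_threshold([5, 5, 5], ["A", "B", "A"])  # constant column
    with pytest.raises(ValueError):
        best_threshold([1, 2, 3], ["A", "A", "A"])  # one class: zero gain


def test_best_threshold_matches_exhaustive_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        size = int(rng.integers(4, 50))
        values = rng.integers(0, 20, size=size).astype(float)
        labels = rng.integers(0, 3, size=size)
        if np.unique(values).size < 2 or np.unique(labels).size < 2:
            continue
        oracle = exhaustive_best_threshold(values, labels)
        if oracle[1] <= 0:
            with pytest.raises(ValueError):
                best_threshold(values, labels)
            continue
        assert best_threshold(values, labels) == pytest.approx(oracle[0])


# ------------------------------------------------------------------- splits

def _binary_cohort():
    schema = make_schema(["250"], with_demo=True)
    X = np.array([[20, 0, 1], [25, 1, 1], [35, 0, 1], [40, 1, 1],
                  [50, 0, 0], [60, 1, 0]], dtype=float)
    y = np.array(["A", "A", "B", "B", "C", "C"])
    return Cohort(X, y, schema)


def test_split_by_presence_partitions_exactly():
    co = _binary_cohort()
    sat, unsat = split_node(co, SplitCondition("250", BINARY_PRESENCE))
    assert (sat.n_samples, unsat.n_samples) == (4, 2)
    assert (sat.column("250") == 1).all() and (unsat.column("250") == 0).all()
    assert sat.n_samples + unsat.n_samples == co.n_samples


def test_split_by_age_threshold():
    co = _binary_cohort()
    sat, unsat = split_node(co, SplitCondition("age", THRESHOLD, 30.0))
    assert (sat.n_samples, unsat.n_samples) == (2, 4)
    assert (sat.column("age") < 30).all()


def test_split_on_constant_feature_is_degenerate():
    co = _binary_cohort()
    zero = Cohort(np.column_stack([co.X[:, 0], co.X[:, 1], np.zeros(6)]),
                  co.y, co.schema)
    sat, unsat = split_node(zero, SplitCondition("250", BINARY_PRESENCE))
    assert sat.n_samples == 0 and unsat.n_samples == 6


def test_weighted_child_entropy_never_exceeds_parent():
    rng = np.random.default_rng(9)
    for _ in range(30):
        size = int(rng.integers(6, 40))
        ages = rng.integers(20, 80, size=size).astype(float)
        y = rng.integers(0, 3, size=size)
        if np.unique(ages).size < 2 or np.unique(y).size < 2:
            continue
        try:
            t = best_threshold(ages, y)
        except ValueError:
            continue
        m = ages < t
        p = m.mean()
        child = p * entropy_bits(y[m]) + (1 - p) * entropy_bits(y[~m])
        assert child <= entropy_bits(y) + 1e-12


# ----------------------------------------------------------------- building

def test_single_class_cohort_gives_one_leaf():
    schema = make_schema(["250"])
    co = Cohort(np.array([[1.0], [0.0]]), np.array(["A", "A"]), schema)
    tree = build_tree(co)
    assert tree.root.is_leaf and tree.root.predominant_class == "A"


def test_planted_markers_give_shallow_perfect_tree():
    co = generate_cohort(marker_spec(per_class=100), seed=4)
    tree = build_tree(co, purity_stop=1.0, min_node_size=1, max_depth=10)
    assert tree.root.condition.feature in {"mkA", "mkB", "mkC"}
    assert tree.depth() <= 3
    assert (predict(tree, co.X) == co.y).all()


def test_demo_structure_split_sequence(demo_cohort):
    tree = build_tree(demo_cohort, max_depth=4)
    root = tree.root
    assert root.condition.feature == "250"
    comorbid = root.children[0]  # '250' present
    assert comorbid.condition.feature == "N05AL"
    rest = comorbid.children[1]  # 'N05AL' absent
    assert rest.condition.feature == "496"


def test_interactive_selector_drives_splits(demo_cohort):
    seen = []

    def pick_last(ctx):
        seen.append(ctx["candidates"])
        assert ctx["projection"] is not None
        assert set(ctx["scores"].table.columns) >= {"feature", "score"}
        return ctx["candidates"][-1]

    tree = build_tree(demo_cohort, selector=pick_last, max_depth=3)
    assert seen and all(e["chooser"] == "interactive" for e in tree.build_log)
    assert tree.root.condition.feature == seen[0][-1]


def test_interactive_selector_unknown_feature_is_error(demo_cohort):
    with pytest.raises(ValueError, match="candidates"):
        build_tree(demo_cohort, selector=lambda ctx: "no-such-code", max_depth=3)


def test_binary_feature_not_reused_on_a_path(demo_cohort):
    tree = build_tree(demo_cohort, purity_stop=1.0, min_node_size=1, max_depth=10)

    def walk(node, used):
        if node.is_leaf:
            return
        f = node.condition.feature
        if node.condition.kind == BINARY_PRESENCE:
            assert f not in used
            used = used | {f}
        for child in node.children:
            walk(child, used)

    walk(tree.root, frozenset())


def test_every_sample_reaches_exactly_one_leaf_with_consistent_counts(demo_cohort):
    tree = build_tree(demo_cohort, max_depth=6)

    def routed_counts(node, mask):
        if node.is_leaf:
            counts = {c: int(((demo_cohort.y == c) & mask).sum()) for c in tree.classes}
            assert counts == node.class_counts
            return
        col = demo_cohort.column(node.condition.feature)
        sat = (col == 1) if node.condition.kind == BINARY_PRESENCE \
            else (col < node.condition.threshold)
        routed_counts(node.children[0], mask & sat)
        routed_counts(node.children[1], mask & ~sat)

    routed_counts(tree.root, np.ones(demo_cohort.n_samples, dtype=bool))


def test_children_counts_sum_to_parent(demo_cohort):
    tree = build_tree(demo_cohort, max_depth=6)

    def walk(node):
        if node.is_leaf:
            return
        for c in tree.classes:
            assert node.class_counts[c] == sum(ch.class_counts[c] for ch in node.children)
        assert all(ch.level == node.level + 1 for ch in node.children)
        for ch in node.children:
            walk(ch)

    assert tree.root.level == 1
    walk(tree.root)


# --------------------------------------------------------------- prediction

def test_predict_walkthrough_paths(walkthrough_tree):
    # features: ['250', '496', 'N05AL']
    assert predict(walkthrough_tree, np.array([0, 0, 0.0])) == "CRG-5192"
    assert predict(walkthrough_tree, np.array([1, 0, 1.0])) == "CRG-7071"
    assert predict(walkthrough_tree, np.array([1, 1, 0.0])) == "CRG-7071"
    assert predict(walkthrough_tree, np.array([1, 0, 0.0])) == "CRG-6144"


def test_predict_one_leaf_tree():
    schema = make_schema(["250"])
    root = TreeNode({"A": 5}, level=1)
    from sctree.tree import ClassificationTree
    tree = ClassificationTree(root, schema, ["A"], [])
    assert predict(tree, np.array([1.0])) == "A"
    assert predict(tree, np.array([0.0])) == "A"


# ------------------------------------------------------------------ styling

def test_node_style_pure_node_is_darkest():
    s = node_style(TreeNode({"A": 100, "B": 0, "C": 0}, level=1))
    assert s.hue != "white" and s.lightness == pytest.approx(0.35)


def test_node_style_no_clear_majority_is_white():
    s = node_style(TreeNode({"A": 34, "B": 33, "C": 33}, level=1))
    assert s.hue == "white" and s.fill == "#ffffff"


def test_node_style_lightness_linear_in_purity():
    s = node_style(TreeNode({"A": 90, "B": 10, "C": 0}, level=1))
    # purity 0.9 maps linearly from [0.5, 1] onto [0.85, 0.35]
    assert s.lightness == pytest.approx(0.85 - 0.5 * (0.9 - 0.5) / 0.5)


# ---------------------------------------------------------- (de)serialization

def test_tree_json_roundtrip(walkthrough_tree):
    text = serialize_tree(walkthrough_tree)
    back = deserialize_tree(text)
    assert serialize_tree(back) == text
    for x in [np.array([0, 0, 0.0]), np.array([1, 0, 1.0]), np.array([1, 1, 0.0])]:
        assert predict(back, x) == predict(walkthrough_tree, x)


def test_deserialize_malformed_json():
    with pytest.raises(json.JSONDecodeError):
        deserialize_tree("{not json")


def test_export_dot_counts_nodes_and_edges(walkthrough_tree):
    dot = export_dot(walkthrough_tree)
    node_lines = [l for l in dot.splitlines() if "label=" in l and "->" not in l
                  and l.strip().startswith("n")]
    edges = [l for l in dot.splitlines() if "->" in l]
    assert len(node_lines) == 7 and len(edges) == 6  # 3 internal + 4 leaves
    assert dot.count("%") == 4  # leaves carry class percentage


def test_export_dot_single_leaf():
    from sctree.tree import ClassificationTree
    tree = ClassificationTree(TreeNode({"A": 5}, level=1), make_schema(["250"]), ["A"], [])
    dot = export_dot(tree)
    assert "->" not in dot and dot.count("fillcolor") == 1


# -------------------------------------------------------------- level table

def test_feature_level_table(walkthrough_tree):
    table = feature_level_table({"demo": walkthrough_tree})
    assert table.loc["250", "demo"] == (1,)
    assert table.loc["N05AL", "demo"] == (2,)
    assert table.loc["496", "demo"] == (3,)
    assert "401" not in table.index  # never used
    assert max(max(v) for v in table["demo"]) == walkthrough_tree.depth() - 1


def test_feature_level_table_repeated_feature_across_branches(demo_cohort):
    tree = build_tree(demo_cohort, purity_stop=1.0, min_node_size=1, max_depth=10)
    table = feature_level_table({"t": tree})
    levels = [lv for v in table["t"] for lv in v]
    assert max(levels) <= tree.depth() - 1
    assert min(levels) == 1
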