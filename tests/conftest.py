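import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sctree.cohort import Cohort, Feature, FeatureSchema
from sctree.synthetic import CohortSpec, generate_cohort, plant_marker, structured_demo_spec
from sctree.tree import (BINARY_PRESENCE, ClassificationTree, SplitCondition,
                         TreeNode)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_schema(code_names, with_demo=False):
    feats = []
    if with_demo:
        feats += [Feature("age", "continuous", "demographic"),
                  Feature("gender", "binary_demographic", "demographic")]
    feats += [Feature(n, "binary_code", "ICD9CM" if len(n) != 5 else "ATC")
              for n in code_names]
    return FeatureSchema(tuple(feats))


def marker_spec(per_class=200, n_noise=5):
    """Three classes, one perfectly exclusive marker code per class."""
    classes = [("A", per_class), ("B", per_class), ("C", per_class)]
    codes = [(f"noise{i:02d}", "ICD9CM") for i in range(n_noise)]
    presence = pd.DataFrame(0.2, index=[c for c, _ in classes],
                            columns=[n for n, _ in codes])
    spec = CohortSpec(classes=classes, codes=codes, presence=presence,
                      age={"A": (40.0, 10.0), "B": (50.0, 10.0), "C": (60.0, 10.0)})
    for cls, code in [("A", "mkA"), ("B", "mkB"), ("C", "mkC")]:
        spec = plant_marker(spec, cls, code, p_in=1.0, p_out=0.0)
    return spec


@pytest.fixture(scope="session")
def demo_cohort():
    return generate_cohort(structured_demo_spec(), seed=0)


@pytest.fixture(scope="session")
def marker_cohort():
    return generate_cohort(marker_spec(), seed=0)


@pytest.fixture
def walkthrough_tree():
    """Hand-built guided tree: '250' absent -> hypertension-only leaf;
    present -> 'N05AL' present -> pure multi-condition leaf; else '496'
    present -> mostly multi-condition leaf, absent -> comorbid leaf."""
    schema = make_schema(["250", "496", "N05AL"])
    classes = ["CRG-5192", "CRG-6144", "CRG-7071"]

    def leaf(counts, level):
        return TreeNode(dict(zip(classes, counts)), level=level)

    n496 = TreeNode(dict(zip(classes, [2, 105, 93])), level=3,
                    condition=SplitCondition("496", BINARY_PRESENCE),
                    children=(leaf([0, 8, 72], 4), leaf([2, 97, 21], 4)))
    n505 = TreeNode(dict(zip(classes, [2, 107, 193])), level=2,
                    condition=SplitCondition("N05AL", BINARY_PRESENCE),
                    children=(leaf([0, 2, 100], 3), n496))
    root = TreeNode(dict(zip(classes, [200, 110, 195])), level=1,
                    condition=SplitCondition("250", BINARY_PRESENCE),
                    children=(n505, leaf([198, 3, 2], 2)))
    return ClassificationTree(root, schema, classes, [])
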