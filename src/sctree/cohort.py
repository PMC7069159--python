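"""Patient-level clinical-code matrices: loading, encoding and screening.

A cohort is a samples x features matrix whose columns are binary clinical
codes (ICD9-CM disease categories, ATC level-4 drug codes), continuous age
in years, and binary gender, together with a per-sample class label such as
a base Clinical Risk Group (CRG).  Raw codes are truncated to their category
level — the first three alphanumeric characters of an ICD9-CM code, the
first five characters of an ATC code — and binarized: a column records the
presence or absence of a code, never how many times it was recorded.

Screening follows the two-stage protocol used with such matrices: discard
code columns with a zero count over all patients, then keep the k features
with the highest entropy gain against the class label (k = 50 by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._entropy import entropy_bits, gain_ratio_threshold, information_gain_discrete

__all__ = [
    "MalformedCodeError",
    "FeatureSchema",
    "Cohort",
    "truncate_icd9_code",
    "truncate_atc_code",
    "load_cohort",
    "prune_zero_count_features",
    "information_gain",
    "select_top_k_features",
]

BINARY_CODE = "binary_code"
CONTINUOUS = "continuous"
BINARY_DEMOGRAPHIC = "binary_demographic"

_KINDS = (BINARY_CODE, CONTINUOUS, BINARY_DEMOGRAPHIC)


class MalformedCodeError(ValueError):
    """Raised when a clinical code cannot be truncated to its category."""


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # binary_code | continuous | binary_demographic
    system: str  # ICD9CM | ATC | demographic

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature list; order defines column order and tie-breaking."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def index_of(self, name: str) -> int:
        for i, f in enumerate(self.features):
            if f.name == name:
                return i
        raise KeyError(name)

    def kind_of(self, name: str) -> str:
        return self.features[self.index_of(name)].kind

    def is_binary(self, name: str) -> bool:
        return self.kind_of(name) != CONTINUOUS

    def subset(self, names: list[str]) -> "FeatureSchema":
        keep = set(names)
        return FeatureSchema(tuple(f for f in self.features if f.name in keep))


@dataclass
class Cohort:
    """Samples x features value matrix with class labels and a schema."""

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X row count must equal label count")
        if self.X.shape[1] != self.schema.n:
            raise ValueError("X column count must equal schema size")
        if len(self.y) and not len(np.unique(self.y)):
            raise ValueError("class label set must be non-empty")
        for j, f in enumerate(self.schema.features):
            col = self.X[:, j]
            if f.kind != CONTINUOUS and not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(f"binary feature {f.name!r} has values outside {{0,1}}")
            if f.kind == CONTINUOUS and (col < 0).any():
                raise ValueError(f"continuous feature {f.name!r} has negative values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list:
        return sorted(np.unique(self.y).tolist())

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.schema.index_of(name)]

    def select_features(self, names: list[str]) -> "Cohort":
        """Cohort restricted to the named features, preserving schema order."""
        schema = self.schema.subset(names)
        idx = [self.schema.index_of(f.name) for f in schema.features]
        return Cohort(self.X[:, idx], self.y.copy(), schema,
                      None if self.sample_ids is None else self.sample_ids.copy())

    def select_samples(self, indices: np.ndarray) -> "Cohort":
        return Cohort(self.X[indices], self.y[indices], self.schema,
                      None if self.sample_ids is None else self.sample_ids[indices])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.schema.names)
        df.insert(0, "label", self.y)
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        """Write the wide CSV layout: sample_id,label,age,gender,<code>..."""
        df = self.to_frame()
        if "sample_id" not in df.columns:
            df.insert(0, "sample_id", [f"S{i}" for i in range(self.n_samples)])
        df.to_csv(path, index=False)


_ALNUM = re.compile(r"[A-Za-z0-9]")


def truncate_icd9_code(code: str) -> str:
    """Collapse an ICD9-CM code to its 3-alphanumeric-character category.

    Subcategory digits and the dot separator are dropped: ``"250.01"`` maps
    to ``"250"``, ``"V58.61"`` to ``"V58"``.  Idempotent on category codes.
    """
    if not code or not str(code).strip():
        raise MalformedCodeError("empty ICD9-CM code")
    chars = _ALNUM.findall(str(code).strip())
    if len(chars) < 3:
        raise MalformedCodeError(f"ICD9-CM code {code!r} has fewer than 3 alphanumeric characters")
    return "".join(chars[:3]).upper()


def truncate_atc_code(code: str) -> str:
    """Truncate an ATC code to level 4 (first 5 characters).

    The last two digits of a full 7-character ATC code name the chemical
    substance and are omitted: ``"A10BA02"`` maps to ``"A10BA"`` (biguanides).
    Idempotent on 5-character codes.
    """
    c = str(code).strip().upper()
    if len(c) not in (5, 7) or not c.isalnum():
        raise MalformedCodeError(f"ATC code {code!r} must have 5 or 7 alphanumeric characters")
    return c[:5]


_TRUNCATORS = {"ICD9CM": truncate_icd9_code, "ATC": truncate_atc_code}


def _demographic_features() -> list[Feature]:
    return [Feature("age", CONTINUOUS, "demographic"),
            Feature("gender", BINARY_DEMOGRAPHIC, "demographic")]


def _guess_system(name: str) -> str:
    # ATC level-4 codes are 5 characters starting with a letter; ICD9-CM
    # categories are 3 characters (possibly with a leading V/E letter).
    return "ATC" if len(name) == 5 else "ICD9CM"


def load_cohort(path, layout: str = "wide", demographics=None) -> Cohort:
    """Load a cohort from CSV.

    ``wide``: one row per patient with columns
    ``sample_id,label,age,gender,<code>...``; code columns must already hold
    0/1 presence values.

    ``long``: ``path`` holds ``sample_id,code_system,code`` rows and
    ``demographics`` a ``sample_id,label,age,gender`` table.  Codes are
    truncated to their category level (``ICD9CM`` → 3 characters, ``ATC`` →
    5) and pivoted to binary presence; duplicate patient–code pairs collapse
    to a single 1, so the matrix records presence, never multiplicity.
    """
    if layout == "wide":
        df = pd.read_csv(path, dtype={"sample_id": str, "label": str})
        if "label" not in df.columns:
            raise ValueError("wide layout is missing the 'label' column")
        sample_ids = (df["sample_id"].to_numpy() if "sample_id" in df.columns
                      else np.array([f"S{i}" for i in range(len(df))]))
        # demographics are optional: a screened cohort may have dropped them
        demo_feats = []
        if "age" in df.columns:
            if df["age"].isna().any() or not np.issubdtype(df["age"].dtype, np.number):
                raise ValueError("non-numeric or missing age")
            demo_feats.append(Feature("age", CONTINUOUS, "demographic"))
        if "gender" in df.columns:
            if df["gender"].isna().any():
                raise ValueError("missing gender")
            demo_feats.append(Feature("gender", BINARY_DEMOGRAPHIC, "demographic"))
        code_cols = [c for c in df.columns if c not in ("sample_id", "label", "age", "gender")]
        feats = demo_feats + [Feature(c, BINARY_CODE, _guess_system(c)) for c in code_cols]
        cols = [f.name for f in demo_feats] + code_cols
        X = df[cols].to_numpy(dtype=float)
        return Cohort(X, df["label"].to_numpy(), FeatureSchema(tuple(feats)), sample_ids)

    if layout == "long":
        if demographics is None:
            raise ValueError("long layout requires a demographics table")
        codes = pd.read_csv(path, dtype=str)
        demo = pd.read_csv(demographics, dtype={"sample_id": str, "label": str})
        if demo["age"].isna().any() or not np.issubdtype(demo["age"].dtype, np.number):
            raise ValueError("non-numeric or missing age")
        unknown = set(codes["sample_id"]) - set(demo["sample_id"])
        if unknown:
            raise ValueError(f"patients in code table missing from demographics: {sorted(unknown)}")
        trunc = []
        for system, code in zip(codes["code_system"], codes["code"]):
            try:
                fn = _TRUNCATORS[system]
            except KeyError:
                raise ValueError(f"unknown code system {system!r}") from None
            trunc.append(fn(code))
        codes = codes.assign(code=trunc)
        # presence/absence: duplicates collapse to one
        presence = pd.crosstab(codes["sample_id"], codes["code"]).clip(upper=1)
        presence = presence.reindex(index=demo["sample_id"], fill_value=0)
        code_names = sorted(presence.columns.tolist())
        feats = _demographic_features() + [
            Feature(c, BINARY_CODE, _guess_system(c)) for c in code_names
        ]
        X = np.column_stack([
            demo["age"].to_numpy(dtype=float),
            demo["gender"].to_numpy(dtype=float),
            presence[code_names].to_numpy(dtype=float),
        ])
        return Cohort(X, demo["label"].to_numpy(), FeatureSchema(tuple(feats)),
                      demo["sample_id"].to_numpy())

    raise ValueError(f"unknown layout {layout!r}")


def prune_zero_count_features(cohort: Cohort) -> Cohort:
    """Drop binary code features that are zero for every patient.

    Demographics (age, gender) are always kept.
    """
    keep = []
    for j, f in enumerate(cohort.schema.features):
        if f.kind == BINARY_CODE and not cohort.X[:, j].any():
            continue
        keep.append(f.name)
    return cohort.select_features(keep)


def information_gain(values, labels) -> float:
    """Entropy gain in bits of a discrete feature column against the labels.

    Returns H(y) − Σ_v p(v)·H(y | value=v); in [0, H(y)].
    """
    return information_gain_discrete(np.asarray(values), np.asarray(labels))


def feature_gains(cohort: Cohort) -> pd.Series:
    """Information gain of every feature, continuous ones discretized first.

    Age is binarized at its best gain-ratio cut-off (the same rule the tree
    uses for thresholds) so it competes with the binary codes on one scale;
    a constant column scores zero.
    """
    gains = {}
    for j, f in enumerate(cohort.schema.features):
        col = cohort.X[:, j]
        if f.kind == CONTINUOUS:
            try:
                t, _ = gain_ratio_threshold(col, cohort.y)
            except ValueError:
                gains[f.name] = 0.0
                continue
            col = (col < t).astype(float)
        gains[f.name] = information_gain_discrete(col, cohort.y)
    return pd.Series(gains)


def select_top_k_features(cohort: Cohort, k: int = 50) -> Cohort:
    """Keep the k features with the highest entropy gain against the label.

    Ties break by schema order so builds are deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > cohort.schema.n:
        raise ValueError(f"k={k} exceeds the {cohort.schema.n} available features")
    gains = feature_gains(cohort)
    order = sorted(range(cohort.schema.n),
                   key=lambda j: (-gains.iloc[j], j))
    chosen = {cohort.schema.features[j].name for j in order[:k]}
    return cohort.select_features([n for n in cohort.schema.names if n in chosen])


def label_entropy(labels) -> float:
    """Entropy of a label vector in bits."""
    return entropy_bits(np.asarray(labels))
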