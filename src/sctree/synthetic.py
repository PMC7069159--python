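"""Synthetic chronic-patient cohort generator.

Real multi-morbidity cohorts stratified into mutually exclusive health
statuses (base Clinical Risk Groups) are private, so this module generates
cohorts with the statistical structure the analysis assumes: per-class
Bernoulli presence rates for binary diagnosis (ICD9-CM category) and drug
(ATC level-4) codes, optional per-(class, code) dropout emulating diagnosis
under-coding (e.g. hypertensive patients lacking the hypertension code),
per-class Gaussian age truncated at zero and rounded to whole years, and
Bernoulli gender.  Codes are independent given the class — the simplest
structure that exercises projection, tree construction and evaluation.

``default_paper_like_spec`` encodes a five-status chronic-disease cohort
(healthy; hypertension; diabetes; both; both plus another dominant chronic
disease) with the classes' published age means and the qualitative presence
pattern of the most common codes.  ``plant_marker`` injects a perfectly (or
partially) class-exclusive code, giving recovery tests a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (BINARY_CODE, BINARY_DEMOGRAPHIC, CONTINUOUS, Cohort,
                     Feature, FeatureSchema)

__all__ = [
    "CohortSpec",
    "default_paper_like_spec",
    "structured_demo_spec",
    "generate_cohort",
    "plant_marker",
    "truncated_age_moments",
]


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``presence`` (and the optional ``dropout``) are class × code probability
    tables; the effective rate of a code in a class is
    presence · (1 − dropout).  ``age`` maps each class to (mean, std) in
    years of a Gaussian truncated at zero.
    """

    classes: list[tuple[str, int]]  # (label, size)
    codes: list[tuple[str, str]]  # (name, system: ICD9CM | ATC)
    presence: pd.DataFrame  # index = class labels, columns = code names
    age: dict  # label -> (mean, std)
    gender_p: float = 0.5
    dropout: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.classes]
        names = [n for n, _ in self.codes]
        self.presence = self.presence.reindex(index=labels, columns=names)
        if self.presence.isna().any().any():
            raise ValueError("presence matrix does not cover every class × code pair")
        if ((self.presence < 0) | (self.presence > 1)).any().any():
            raise ValueError("presence probabilities must be in [0, 1]")
        if self.dropout is not None:
            self.dropout = self.dropout.reindex(index=labels, columns=names).fillna(0.0)
            if ((self.dropout < 0) | (self.dropout > 1)).any().any():
                raise ValueError("dropout probabilities must be in [0, 1]")
        if any(s < 1 for _, s in self.classes):
            raise ValueError("class sizes must be >= 1")
        if not 0 <= self.gender_p <= 1:
            raise ValueError("gender_p must be in [0, 1]")
        for label in labels:
            if label not in self.age:
                raise ValueError(f"missing age parameters for class {label!r}")

    @property
    def labels(self) -> list[str]:
        return [c for c, _ in self.classes]

    @property
    def code_names(self) -> list[str]:
        return [n for n, _ in self.codes]

    def effective_presence(self) -> pd.DataFrame:
        """Presence after under-coding dropout: presence · (1 − dropout)."""
        if self.dropout is None:
            return self.presence.copy()
        return self.presence * (1.0 - self.dropout)

    def schema(self) -> FeatureSchema:
        feats = [Feature("age", CONTINUOUS, "demographic"),
                 Feature("gender", BINARY_DEMOGRAPHIC, "demographic")]
        feats += [Feature(n, BINARY_CODE, s) for n, s in self.codes]
        return FeatureSchema(tuple(feats))

    def to_dict(self) -> dict:
        return {
            "classes": [[c, int(s)] for c, s in self.classes],
            "codes": [[n, s] for n, s in self.codes],
            "presence": {c: self.presence.loc[c].tolist() for c in self.labels},
            "age": {c: list(map(float, self.age[c])) for c in self.labels},
            "gender_p": self.gender_p,
            "dropout": None if self.dropout is None else
                       {c: self.dropout.loc[c].tolist() for c in self.labels},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        codes = [tuple(x) for x in d["codes"]]
        names = [n for n, _ in codes]
        presence = pd.DataFrame.from_dict(d["presence"], orient="index")
        presence.columns = names
        dropout = None
        if d.get("dropout") is not None:
            dropout = pd.DataFrame.from_dict(d["dropout"], orient="index")
            dropout.columns = names
        return cls(
            classes=[(c, int(s)) for c, s in d["classes"]],
            codes=codes,
            presence=presence,
            age={c: tuple(v) for c, v in d["age"].items()},
            gender_p=float(d.get("gender_p", 0.5)),
            dropout=dropout,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(text))


# Published class sizes of the five-status chronic cohort the defaults
# emulate; the generator ships them scaled down for desk-scale runs.
_FULL_SIZES = {
    "CRG-1000": 46835,  # healthy
    "CRG-5192": 12447,  # hypertension
    "CRG-5424": 2166,   # diabetes
    "CRG-6144": 3179,   # diabetes + hypertension
    "CRG-7071": 547,    # diabetes + hypertension + other dominant chronic disease
}
_AGES = {
    "CRG-1000": (26.0, 15.0),
    "CRG-5192": (54.0, 14.0),
    "CRG-5424": (49.0, 15.0),
    "CRG-6144": (62.0, 11.0),
    "CRG-7071": (66.0, 12.0),
}


def default_paper_like_spec(scale: float = 0.02, floor: int = 100,
                            n_noise_codes: int = 5) -> CohortSpec:
    """Five-class chronic-cohort spec with published age parameters.

    Class sizes are ``scale`` times the full cohort's (floored at ``floor``
    per class so even the rarest status is testable).  Presence rates encode
    the qualitative pattern of the most frequent codes: the hypertension
    code '401' is near-universal among hypertensive statuses but dropped in
    ~25% of the single-condition hypertensive class (under-coding); the
    diabetes code '250' is likewise missing in ~15% of pure diabetics;
    healthy patients carry chronic codes at low but nonzero rates.
    ``n_noise_codes`` uninformative codes (rate 0.1 everywhere) are added.
    """
    classes = [(c, max(floor, round(scale * s))) for c, s in _FULL_SIZES.items()]
    codes = [
        ("250", "ICD9CM"), ("272", "ICD9CM"), ("401", "ICD9CM"),
        ("496", "ICD9CM"), ("724", "ICD9CM"),
        ("A10BA", "ATC"), ("C09AA", "ATC"), ("C10AA", "ATC"),
        ("N02BE", "ATC"), ("N05AL", "ATC"),
    ]
    #                 250    272    401    496    724   A10BA  C09AA  C10AA  N02BE  N05AL
    presence = {
        "CRG-1000": [0.05, 0.05, 0.06, 0.01, 0.10, 0.02, 0.02, 0.05, 0.25, 0.01],
        "CRG-5192": [0.06, 0.35, 1.00, 0.05, 0.15, 0.03, 0.55, 0.40, 0.45, 0.02],
        "CRG-5424": [1.00, 0.35, 0.10, 0.05, 0.25, 0.70, 0.08, 0.45, 0.45, 0.02],
        "CRG-6144": [0.90, 0.45, 0.85, 0.08, 0.25, 0.75, 0.60, 0.55, 0.55, 0.03],
        "CRG-7071": [0.92, 0.50, 0.88, 0.45, 0.30, 0.78, 0.62, 0.60, 0.65, 0.35],
    }
    dropout = {c: [0.0] * len(codes) for c in presence}
    dropout["CRG-5192"][2] = 0.25  # hypertensives lacking '401'
    dropout["CRG-5424"][0] = 0.15  # diabetics lacking '250'
    noise = [(f"noise{i:02d}", "ICD9CM") for i in range(n_noise_codes)]
    for c in presence:
        presence[c] = presence[c] + [0.10] * n_noise_codes
        dropout[c] = dropout[c] + [0.0] * n_noise_codes
    all_codes = codes + noise
    names = [n for n, _ in all_codes]
    return CohortSpec(
        classes=classes,
        codes=all_codes,
        presence=pd.DataFrame.from_dict(presence, orient="index", columns=names),
        age=dict(_AGES),
        gender_p=0.5,
        dropout=pd.DataFrame.from_dict(dropout, orient="index", columns=names),
    )


def structured_demo_spec(per_class: int = 200) -> CohortSpec:
    """Three-class comorbidity spec with a known split hierarchy.

    Encodes the canonical guided-tree walkthrough: the diabetes code '250'
    is absent from the pure-hypertension class and near-universal in the two
    comorbid classes, so it splits the first from the rest; among the
    comorbid classes the antipsychotic code 'N05AL' occurs only in the
    multi-condition class and isolates part of it exactly; the obstructive
    airway code '496' then marks most of the remainder of that class.
    Background codes ('401', 'C09AA', 'N02BE') are common everywhere and
    carry little separation.
    """
    classes = [("CRG-5192", per_class), ("CRG-6144", per_class), ("CRG-7071", per_class)]
    codes = [("250", "ICD9CM"), ("496", "ICD9CM"), ("401", "ICD9CM"),
             ("C09AA", "ATC"), ("N02BE", "ATC"), ("N05AL", "ATC")]
    #                 250    496    401   C09AA  N02BE  N05AL
    presence = {
        "CRG-5192": [0.02, 0.02, 0.75, 0.55, 0.45, 0.00],
        "CRG-6144": [0.98, 0.05, 0.85, 0.60, 0.55, 0.00],
        "CRG-7071": [0.98, 0.50, 0.88, 0.62, 0.65, 0.60],
    }
    names = [n for n, _ in codes]
    return CohortSpec(
        classes=classes,
        codes=codes,
        presence=pd.DataFrame.from_dict(presence, orient="index", columns=names),
        age={"CRG-5192": (54.0, 14.0), "CRG-6144": (62.0, 11.0), "CRG-7071": (66.0, 12.0)},
    )


def truncated_age_moments(mean: float, std: float) -> tuple[float, float]:
    """Mean and std in years implied by a Gaussian(mean, std) truncated at 0."""
    a = (0.0 - mean) / std
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=std)
    return float(dist.mean()), float(dist.std())


def generate_cohort(spec: CohortSpec, seed: int = 0) -> Cohort:
    """Draw a cohort from a spec; identical (spec, seed) → identical cohort.

    Per class: each code is Bernoulli with its presence rate, then zeroed
    with its dropout rate (under-coding); age is Gaussian truncated at 0 and
    rounded to whole years; gender is Bernoulli(gender_p).
    """
    rng = np.random.default_rng(seed)
    schema = spec.schema()
    blocks, labels = [], []
    for label, size in spec.classes:
        p = spec.presence.loc[label].to_numpy(dtype=float)
        codes = (rng.random((size, len(p))) < p).astype(float)
        if spec.dropout is not None:
            d = spec.dropout.loc[label].to_numpy(dtype=float)
            keep = rng.random((size, len(d))) >= d
            codes *= keep
        mu, sd = spec.age[label]
        a = (0.0 - mu) / sd
        age = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size,
                                  random_state=rng)
        age = np.round(age)
        gender = (rng.random(size) < spec.gender_p).astype(float)
        blocks.append(np.column_stack([age, gender, codes]))
        labels.extend([label] * size)
    X = np.vstack(blocks)
    y = np.asarray(labels)
    ids = np.array([f"S{i:05d}" for i in range(len(y))])
    return Cohort(X, y, schema, ids)


def plant_marker(spec: CohortSpec, target_class: str, code: str,
                 p_in: float = 1.0, p_out: float = 0.0,
                 system: str = "ICD9CM") -> CohortSpec:
    """Spec with ``code`` present at rate ``p_in`` in ``target_class`` and
    ``p_out`` elsewhere — a ground-truth discriminative feature.

    The code is appended to the spec if new; the class must already exist.
    """
    for p in (p_in, p_out):
        if not 0 <= p <= 1:
            raise ValueError("marker probabilities must be in [0, 1]")
    if target_class not in spec.labels:
        raise ValueError(f"unknown class {target_class!r}")
    codes = list(spec.codes)
    presence = spec.presence.copy()
    dropout = None if spec.dropout is None else spec.dropout.copy()
    if code not in spec.code_names:
        codes.append((code, system))
        presence[code] = p_out
        if dropout is not None:
            dropout[code] = 0.0
    presence.loc[:, code] = p_out
    presence.loc[target_class, code] = p_in
    return CohortSpec(
        classes=list(spec.classes),
        codes=codes,
        presence=presence,
        age=dict(spec.age),
        gender_p=spec.gender_p,
        dropout=dropout,
    )
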