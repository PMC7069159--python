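"""Star-coordinates LDA projections and discriminative feature scores.

Linear discriminant analysis (LDA) finds the 2-D linear projection that
maximizes between-class relative to within-class variance.  Rendered as star
coordinates, the rows of the projection matrix become one 2-D axis vector
v_i per feature, and a sample x maps to the plane as p = Σ_i x̃_i · v_i
(x̃ the standardized feature values).  The length of v_i and its orientation
relative to the direction that separates a class from the rest quantify how
discriminative feature i is — the rule a domain expert applies visually when
choosing split features, formalized here as the score |v_i · d̂|.

Within-class scatter is ridge-regularized (S_W + ridge·I) because deep tree
nodes hold few samples and near-constant binary columns; constant columns
are dropped from the local fit and assigned zero axis vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .cohort import CONTINUOUS, Cohort, FeatureSchema

__all__ = [
    "ProjectionModel",
    "FeatureScoreTable",
    "fit_lda_projection",
    "sc_project",
    "separating_direction",
    "discriminative_scores",
]


@dataclass
class ProjectionModel:
    """A fitted 2-D LDA mapping expressed as star-coordinates axis vectors.

    ``axis_vectors`` has one row per schema feature (zero rows for columns
    that were constant at fit time); ``center``/``scale`` standardize inputs
    before projection; ``class_centroids`` are the per-class means of the
    projected training samples and ``class_counts`` their sizes.
    """

    axis_vectors: np.ndarray  # n x 2
    center: np.ndarray
    scale: np.ndarray
    classes: list
    class_centroids: dict
    class_counts: dict
    ridge: float
    feature_names: list[str]
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def n_features(self) -> int:
        return self.axis_vectors.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis_vectors": self.axis_vectors.tolist(),
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
                "classes": list(self.classes),
                "class_centroids": {str(c): v.tolist() for c, v in self.class_centroids.items()},
                "class_counts": {str(c): int(v) for c, v in self.class_counts.items()},
                "ridge": self.ridge,
                "feature_names": self.feature_names,
                "eigenvalues": self.eigenvalues.tolist(),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProjectionModel":
        d = json.loads(text)
        return cls(
            axis_vectors=np.asarray(d["axis_vectors"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            classes=d["classes"],
            class_centroids={c: np.asarray(v, dtype=float) for c, v in d["class_centroids"].items()},
            class_counts={c: int(v) for c, v in d["class_counts"].items()},
            ridge=float(d["ridge"]),
            feature_names=list(d["feature_names"]),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
        )


@dataclass
class FeatureScoreTable:
    """Per-(feature, target class) discriminance scores.

    ``table`` holds one row per pair with the axis-vector length, the cosine
    alignment with the class-separating unit direction d̂, and the score
    |v_i · d̂|; ``directions`` maps each target class to its d̂.
    """

    table: pd.DataFrame  # columns: feature, target_class, length, alignment, score
    directions: dict

    def max_scores(self) -> pd.Series:
        """Per-feature maximum score over target classes, in schema order."""
        order = self.table["feature"].drop_duplicates().tolist()
        s = self.table.groupby("feature", sort=False)["score"].max()
        return s.reindex(order)

    def ranking(self) -> list[str]:
        """Features by descending max-over-classes score; ties by schema order."""
        s = self.max_scores()
        return sorted(s.index.tolist(), key=lambda f: (-s[f], s.index.get_loc(f)))


def _scatter_matrices(Xs: np.ndarray, y: np.ndarray):
    """Within/between-class scatter (covariance-scaled) of standardized data."""
    n = Xs.shape[0]
    mu = Xs.mean(axis=0)
    sw = np.zeros((Xs.shape[1], Xs.shape[1]))
    sb = np.zeros_like(sw)
    for c in np.unique(y):
        Xc = Xs[y == c]
        mc = Xc.mean(axis=0)
        d = Xc - mc
        sw += d.T @ d
        g = (mc - mu)[:, None]
        sb += len(Xc) * (g @ g.T)
    return sw / n, sb / n


def fit_lda_projection(
    X: np.ndarray,
    y: np.ndarray,
    schema: FeatureSchema | None = None,
    ridge: float | None = None,
) -> ProjectionModel:
    """Fit the 2-D LDA projection of (X, y) as star-coordinates axis vectors.

    Features are centered; continuous features are additionally scaled to
    unit variance so age in years cannot dominate the binary codes.  The axis
    vectors are the top-2 generalized eigenvectors of (S_B, S_W + ridge·I)
    scaled so vᵀ(S_W + ridge·I)v = 1, each axis sign-fixed so its largest
    coefficient is positive.  With two classes only one discriminant
    direction exists and the second column is all-zero.

    ``ridge`` defaults to 1e-3 · tr(S_W)/n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("LDA requires at least 2 classes")
    n_feat = X.shape[1]
    names = schema.names if schema is not None else [f"f{i}" for i in range(n_feat)]

    center = X.mean(axis=0)
    scale = np.ones(n_feat)
    if schema is not None:
        for j, f in enumerate(schema.features):
            if f.kind == CONTINUOUS:
                s = X[:, j].std()
                if s > 0:
                    scale[j] = s
    Xs = (X - center) / scale

    active = np.where(Xs.std(axis=0) > 1e-12)[0]
    V = np.zeros((n_feat, 2))
    if active.size == 0:
        raise ValueError("all features constant; nothing to project")
    Xa = Xs[:, active]
    sw, sb = _scatter_matrices(Xa, y)
    if ridge is None:
        ridge = 1e-3 * np.trace(sw) / max(1, len(active))
    ridge = float(ridge)
    sw_reg = sw + ridge * np.eye(len(active))

    k = min(2, len(classes) - 1, len(active))
    lo = len(active) - k
    w, vecs = scipy.linalg.eigh(sb, sw_reg, subset_by_index=[lo, len(active) - 1])
    # eigh returns ascending order; flip to put the leading axis first
    w, vecs = w[::-1], vecs[:, ::-1]
    for j in range(k):
        col = vecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            col = -col
        V[active, j] = col

    eigenvalues = np.zeros(2)
    eigenvalues[:k] = w[:k]

    model = ProjectionModel(
        axis_vectors=V,
        center=center,
        scale=scale,
        classes=classes,
        class_centroids={},
        class_counts={c: int((y == c).sum()) for c in classes},
        ridge=ridge,
        feature_names=list(names),
        eigenvalues=eigenvalues,
    )
    P = sc_project(model, X)
    model.class_centroids = {c: P[y == c].mean(axis=0) for c in classes}
    return model


def sc_project(model: ProjectionModel, x: np.ndarray) -> np.ndarray:
    """Map sample(s) to the plane: p = Σ_i x̃_i · v_i.

    Accepts a single feature vector (returns a 2-vector) or a sample matrix
    (returns an m x 2 array).  Exactly linear in the standardized values.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    P = model.standardize(X) @ model.axis_vectors
    return P[0] if single else P


def separating_direction(model: ProjectionModel, target_class) -> np.ndarray:
    """Unit 2-D direction from the rest-of-cohort centroid to the target class.

    One-vs-rest: the non-target centroid pools every other class's projected
    samples (class centroids weighted by class size).  Raises ``ValueError``
    when the centroids coincide.
    """
    if target_class not in model.class_centroids:
        raise ValueError(f"unknown class {target_class!r}")
    others = [c for c in model.classes if c != target_class]
    wsum = sum(model.class_counts[c] for c in others)
    rest = sum(model.class_counts[c] * model.class_centroids[c] for c in others) / wsum
    d = model.class_centroids[target_class] - rest
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError(f"class {target_class!r} centroid coincides with the rest; no separating direction")
    return d / norm


def discriminative_scores(
    model: ProjectionModel, classes_to_separate=None
) -> FeatureScoreTable:
    """Score every feature's power to separate each target class.

    For target class c with separating unit direction d̂(c), feature i scores
    |v_i · d̂(c)| — long vectors pointing along the separation score high,
    vectors orthogonal to it score zero however long.  Classes whose centroid
    coincides with the rest are skipped (nothing separates them in the plane).
    """
    targets = list(classes_to_separate) if classes_to_separate is not None else list(model.classes)
    rows = []
    directions = {}
    lengths = np.linalg.norm(model.axis_vectors, axis=1)
    for c in targets:
        try:
            d = separating_direction(model, c)
        except ValueError:
            continue
        directions[c] = d
        proj = model.axis_vectors @ d
        with np.errstate(invalid="ignore", divide="ignore"):
            align = np.where(lengths > 0, proj / np.where(lengths > 0, lengths, 1.0), 0.0)
        for i, name in enumerate(model.feature_names):
            rows.append((name, c, lengths[i], align[i], abs(proj[i])))
    if not rows:
        raise ValueError("no target class admits a separating direction")
    table = pd.DataFrame(rows, columns=["feature", "target_class", "length", "alignment", "score"])
    return FeatureScoreTable(table=table, directions=directions)


def fit_node_projection(cohort: Cohort, ridge: float | None = None) -> ProjectionModel:
    """Convenience: fit the projection for a cohort with its schema."""
    return fit_lda_projection(cohort.X, cohort.y, schema=cohort.schema, ridge=ridge)
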