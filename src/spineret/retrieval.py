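"""Archive, similarity matching and gated retrieval.

Two retrieval architectures are implemented over a shared enrolment
archive of (id, class, feature) records:

* SA (standard architecture): the query feature is ranked against the
  whole archive by distance;
* PA (proposed/classifier-gated architecture): a trained gating
  classifier first predicts the query's irregularity class; only
  archive records pre-classified to that class are ranked.

The default similarity is a weighted city-block distance with inverse
standard-deviation weights computed at enrolment (plain city-block and
chi-square are selectable).  Ranking is total and deterministic:
ascending distance, ties broken by record id.  A query that is itself
an archive member is excluded from its own candidate set.

Retrieval quality is summarized by Pr@M -- the percentage of the M
topmost hits sharing the query's true class -- for M in {5, 10, 15, 20}
and by the average group score A_GS, the arithmetic mean of the four
Pr@M values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import NormalizationParams, apply_normalizer, fit_normalizer

__all__ = [
    "Archive",
    "RankedRetrieval",
    "RetrievalMetrics",
    "enrol",
    "similarity",
    "retrieve",
    "precision_at",
    "ags",
    "evaluate_retrieval",
]

STANDARD_M = (5, 10, 15, 20)
EPS = 1e-9
METRICS = ("cityblock", "weighted-cityblock", "chi-square")


@dataclass
class Archive:
    """Enrolment store of (class, feature) records with shared scaling."""

    ids: list
    classes: list
    features: np.ndarray  # raw feature matrix (n, d)
    normalizer: NormalizationParams
    normalized: np.ndarray  # (n, d) in [0, 1]
    sigma: np.ndarray  # per-dimension std of normalized features
    algorithm: str = ""
    representation: str = ""
    predicted_classes: list | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def classify(self, model) -> None:
        """Pre-classify every record with the gating classifier."""
        self.predicted_classes = [model.predict(f) for f in self.features]


@dataclass
class RankedRetrieval:
    query_id: str
    hits: list  # (record id, class, distance), non-decreasing distance
    architecture: str
    m_requested: int
    predicted_class: str | None = None
    status: str = "ok"


@dataclass
class RetrievalMetrics:
    pr_at: dict  # {M: percentage}
    a_gs: float


def enrol(items, algorithm: str = "", representation: str = "") -> Archive:
    """Build the archive from (id, class, feature) triples.

    Fits the shared min-max normalizer and the per-dimension standard
    deviations used by the weighted city-block metric.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot enrol an empty collection")
    ids = [it[0] for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in enrolment")
    classes = [it[1] for it in items]
    features = np.asarray([np.asarray(it[2], dtype=float).ravel() for it in items])
    if features.ndim != 2:
        raise ValueError("inconsistent feature dimensionality")
    normalizer = fit_normalizer(features)
    normalized = apply_normalizer(normalizer, features)
    sigma = normalized.std(axis=0)
    return Archive(ids, classes, features, normalizer, normalized, sigma,
                   algorithm, representation)


def similarity(
    f_q: np.ndarray,
    f_i: np.ndarray,
    weights: np.ndarray | None = None,
    metric: str = "weighted-cityblock",
) -> float:
    """Distance between two feature vectors (symmetric, 0 iff equal).

    cityblock: sum |q - i|;  weighted-cityblock: sum w |q - i|;
    chi-square: sum (q - i)^2 / (q + i + eps).
    """
    f_q = np.asarray(f_q, dtype=float).ravel()
    f_i = np.asarray(f_i, dtype=float).ravel()
    if f_q.shape != f_i.shape:
        raise ValueError("feature dimension mismatch")
    if metric == "cityblock":
        return float(np.abs(f_q - f_i).sum())
    if metric == "weighted-cityblock":
        w = np.ones_like(f_q) if weights is None else np.asarray(weights, dtype=float)
        return float((w * np.abs(f_q - f_i)).sum())
    if metric == "chi-square":
        return float(((f_q - f_i) ** 2 / (f_q + f_i + EPS)).sum())
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def inverse_sigma_weights(archive: Archive) -> np.ndarray:
    """Differential dimension weights 1 / (sigma + eps)."""
    return 1.0 / (archive.sigma + EPS)


def retrieve(
    query_feature: np.ndarray,
    archive: Archive,
    m: int = 20,
    architecture: str = "SA",
    model=None,
    query_id: str | None = None,
    metric: str = "weighted-cityblock",
) -> RankedRetrieval:
    """Rank archive records against a raw query feature vector.

    SA ranks the whole archive.  PA predicts the query's class with the
    gating classifier and ranks only records pre-classified to that
    class (records are classified on demand if :meth:`Archive.classify`
    has not been called).  ``query_id`` excludes the query's own archive
    record (leave-one-out retrieval).
    """
    if architecture not in ("SA", "PA"):
        raise ValueError("architecture must be 'SA' or 'PA'")
    q_raw = np.asarray(query_feature, dtype=float).ravel()
    qn = apply_normalizer(archive.normalizer, q_raw)
    weights = inverse_sigma_weights(archive)

    predicted = None
    if architecture == "PA":
        if model is None:
            raise ValueError("PA retrieval requires a trained gating classifier")
        predicted = model.predict(q_raw)
        if archive.predicted_classes is None:
            archive.classify(model)
        candidates = [i for i, c in enumerate(archive.predicted_classes)
                      if c == predicted]
    else:
        candidates = list(range(len(archive)))
    if query_id is not None:
        candidates = [i for i in candidates if archive.ids[i] != query_id]
    if not candidates:
        return RankedRetrieval(query_id or "", [], architecture, m,
                               predicted_class=predicted, status="no-candidates")

    dists = [similarity(qn, archive.normalized[i], weights, metric)
             for i in candidates]
    order = sorted(range(len(candidates)),
                   key=lambda j: (dists[j], archive.ids[candidates[j]]))[:m]
    hits = [(archive.ids[candidates[j]], archive.classes[candidates[j]], dists[j])
            for j in order]
    return RankedRetrieval(query_id or "", hits, architecture, m,
                           predicted_class=predicted)


def precision_at(relevance_flags, m: int) -> float:
    """Pr@M: percentage of relevant hits among the M topmost results."""
    flags = list(relevance_flags)
    if len(flags) != m:
        raise ValueError(f"expected exactly {m} relevance flags, got {len(flags)}")
    if m not in STANDARD_M:
        import warnings

        warnings.warn(f"non-standard cut-off M={m}", stacklevel=2)
    return 100.0 * sum(bool(f) for f in flags) / m


def ags(pr_values) -> float:
    """Average group score: arithmetic mean of the four Pr@M values."""
    vals = [float(v) for v in pr_values]
    if len(vals) != len(STANDARD_M):
        raise ValueError(f"A_GS needs exactly {len(STANDARD_M)} Pr@M values")
    return float(np.mean(vals))


def evaluate_retrieval(
    archive: Archive,
    architecture: str = "SA",
    model=None,
    m_values: tuple = STANDARD_M,
    metric: str = "weighted-cityblock",
) -> RetrievalMetrics:
    """Leave-one-out retrieval evaluation over every archived image.

    Every archive record serves once as the query (its own record
    excluded); a hit is relevant when its class equals the query's true
    class.  When gating exhausts a class before M hits, the missing
    positions count as irrelevant.  Reported Pr@M values are means over
    all queries, in percent.
    """
    per_m = {m: [] for m in m_values}
    m_max = max(m_values)
    for i in range(len(archive)):
        result = retrieve(archive.features[i], archive, m=m_max,
                          architecture=architecture, model=model,
                          query_id=archive.ids[i], metric=metric)
        flags = [cls == archive.classes[i] for _, cls, _ in result.hits]
        flags += [False] * (m_max - len(flags))
        for m in m_values:
            per_m[m].append(precision_at(flags[:m], m))
    pr = {m: float(np.mean(v)) for m, v in per_m.items()}
    return RetrievalMetrics(pr, ags([pr[m] for m in STANDARD_M])
                            if set(STANDARD_M) <= set(m_values) else float("nan"))


def save_archive(archive: Archive, outdir: str | Path) -> None:
    """Persist as manifest JSON + features CSV (id, class, v1..vN)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "algorithm": archive.algorithm,
        "representation": archive.representation,
        "normalizer": {"mins": archive.normalizer.mins.tolist(),
                       "maxs": archive.normalizer.maxs.tolist()},
        "sigma": archive.sigma.tolist(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    df = pd.DataFrame(archive.features,
                      columns=[f"v{i+1}" for i in range(archive.features.shape[1])])
    df.insert(0, "class", archive.classes)
    df.insert(0, "id", archive.ids)
    df.to_csv(outdir / "features.csv", index=False)


def load_archive(indir: str | Path) -> Archive:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    df = pd.read_csv(indir / "features.csv")
    features = df[[c for c in df.columns if c.startswith("v")]].to_numpy(float)
    normalizer = NormalizationParams(np.array(manifest["normalizer"]["mins"]),
                                     np.array(manifest["normalizer"]["maxs"]))
    return Archive(
        ids=df["id"].tolist(),
        classes=df["class"].tolist(),
        features=features,
        normalizer=normalizer,
        normalized=apply_normalizer(normalizer, features),
        sigma=np.array(manifest["sigma"]),
        algorithm=manifest["algorithm"],
        representation=manifest["representation"],
    )
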