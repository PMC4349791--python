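"""End-to-end experiment runner.

Reproduces the experimental grid -- feature algorithm x boundary
representation x retrieval architecture -- on synthetic vertebra
datasets: generate labelled images, preprocess, segment with the active
shape model (or take the annotated ground truth), extract the requested
feature families, train the gating classifier, evaluate every archived
image as a leave-one-out query under both the standard and the gated
architecture, and tabulate Pr@M and A_GS per algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as draw_polygon

from . import asm as asm_mod
from .classifier import roc_auc_multiclass, train_pmcvnn
from .contour_features import contour_feature_set
from .preprocessing import PreprocessConfig, preprocess
from .region_features import GaborBank, region_feature_set
from .retrieval import STANDARD_M, enrol, evaluate_retrieval
from .shapes import (
    Contour,
    NinePointShape,
    bspline_control_points,
    resample_contour,
)
from .synthetic import Dataset, SyntheticSpec, make_dataset

logger = logging.getLogger("spineret")

REGION_ALGORITHMS = ("GW", "GLCM", "RT", "OH")
CONTOUR_ALGORITHMS = ("GSP", "FD-CD", "FD-CC")
ALL_ALGORITHMS = REGION_ALGORITHMS + CONTOUR_ALGORITHMS
REPRESENTATIONS = ("9-APR", "B-SR")
SIGNATURE_SAMPLES = 128


@dataclass
class ExperimentConfig:
    """One experiment: dataset conditions, representation, algorithms."""

    region: str = "cervical"
    per_class: int = 22
    image_size: int = 128
    noise_level: float = 0.05
    blur_sigma: float = 1.0
    seed: int = 0
    representation: str = "9-APR"
    algorithms: tuple = ALL_ALGORITHMS
    segmentation: str = "asm"  # asm | ground-truth
    init_jitter_px: float = 3.0  # ASM initialization perturbation
    classifier_hidden: int = 20
    cv_folds: int = 5
    metric: str = "weighted-cityblock"
    m_values: tuple = STANDARD_M
    outdir: str | None = None

    def __post_init__(self):
        if not self.algorithms:
            raise ValueError("at least one feature algorithm required")
        unknown = set(self.algorithms) - set(ALL_ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.segmentation not in ("asm", "ground-truth"):
            raise ValueError("segmentation must be 'asm' or 'ground-truth'")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a flat YAML mapping into an :class:`ExperimentConfig`."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    if "algorithms" in data:
        data["algorithms"] = tuple(data["algorithms"])
    if "m_values" in data:
        data["m_values"] = tuple(data["m_values"])
    return ExperimentConfig(**data)


def representation_landmarks(shape: NinePointShape, representation: str) -> np.ndarray:
    """Landmark set used by the ASM: 9-APR points or 27 B-SR control points."""
    if representation == "9-APR":
        return shape.points.copy()
    return bspline_control_points(shape)


def representation_contour(landmarks: np.ndarray, representation: str) -> Contour:
    """Boundary contour (arc-length uniform) from fitted landmarks.

    9-APR landmarks trace the canonical polygon directly (coincident
    osteophyte points collapsed); B-SR landmarks are the 27 control
    points of the closed cubic spline, which is evaluated densely before
    resampling.
    """
    from .shapes import _collapse_duplicates, evaluate_periodic_bspline

    pts = _collapse_duplicates(np.asarray(landmarks, dtype=float))
    if representation == "B-SR" and len(pts) >= 4:
        dense_t = np.linspace(0, len(pts), 16 * SIGNATURE_SAMPLES, endpoint=False)
        pts = evaluate_periodic_bspline(pts, dense_t)
    return resample_contour(Contour(pts, closed=True), SIGNATURE_SAMPLES)


def rasterize_contour(c: Contour, size: int) -> np.ndarray:
    rr, cc = draw_polygon(c.points[:, 1], c.points[:, 0], shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def segment_dataset(ds: Dataset, cfg: ExperimentConfig) -> list[np.ndarray]:
    """Landmark sets per image: ASM search or annotated ground truth."""
    gt = [representation_landmarks(r.shape, cfg.representation) for r in ds.records]
    if cfg.segmentation == "ground-truth":
        return gt
    pre_cfg = PreprocessConfig()
    images = [preprocess(r.image, pre_cfg) for r in ds.records]
    shape_model, profile_model = asm_mod.train_asm(images, gt)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA5]).generate_state(1)[0])
    fitted = []
    for img, lms in zip(images, gt):
        init = lms + rng.uniform(-cfg.init_jitter_px, cfg.init_jitter_px, size=2)
        fit = asm_mod.asm_search(img, shape_model, profile_model, init)
        fitted.append(fit.landmarks)
    return fitted


def extract_features(
    ds: Dataset,
    landmark_sets: list[np.ndarray],
    cfg: ExperimentConfig,
    bank: GaborBank | None = None,
) -> dict[str, np.ndarray]:
    """Feature matrix per requested algorithm, one row per image."""
    region_algs = tuple(a for a in cfg.algorithms if a in REGION_ALGORITHMS)
    contour_algs = tuple(a for a in cfg.algorithms if a in CONTOUR_ALGORITHMS)
    if region_algs and bank is None:
        bank = GaborBank()
    per_alg: dict[str, list] = {a: [] for a in cfg.algorithms}
    for rec, lms in zip(ds.records, landmark_sets):
        contour = representation_contour(lms, cfg.representation)
        if region_algs:
            mask = rasterize_contour(contour, cfg.image_size)
            for alg, fv in region_feature_set(mask, region_algs, bank=bank).items():
                per_alg[alg].append(fv.values)
        for alg, fv in contour_feature_set(contour, contour_algs).items():
            per_alg[alg].append(fv.values)
    return {a: np.asarray(v) for a, v in per_alg.items()}


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    table: pd.DataFrame  # rows: algorithms (+ Mean), SA and PA blocks
    classifier_auc: dict = field(default_factory=dict)  # algorithm -> CV AUC

    def mean_ags(self, architecture: str) -> float:
        return float(self.table.loc["Mean", f"{architecture}_A_GS"])


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full grid for one dataset and representation.

    Returns the per-algorithm metric table; columns are
    ``SA_Pr@5 .. SA_A_GS, PA_Pr@5 .. PA_A_GS`` plus a ``Mean`` row with
    the per-architecture column means (the headline comparison between
    the two architectures).
    """
    logger.info("generating %s dataset (%d per class, seed %d)",
                cfg.region, cfg.per_class, cfg.seed)
    spec = SyntheticSpec(region=cfg.region, per_class=cfg.per_class,
                         image_size=cfg.image_size, noise_level=cfg.noise_level,
                         blur_sigma=cfg.blur_sigma, seed=cfg.seed)
    ds = make_dataset(spec)

    logger.info("segmenting (%s, %s)", cfg.segmentation, cfg.representation)
    landmark_sets = segment_dataset(ds, cfg)

    logger.info("extracting features: %s", ", ".join(cfg.algorithms))
    features = extract_features(ds, landmark_sets, cfg)

    labels = np.array(ds.labels)
    ids = [r.image_id for r in ds.records]
    rows = {}
    classifier_auc = {}
    for alg in cfg.algorithms:
        X = features[alg]
        model = train_pmcvnn(X, labels, k=cfg.cv_folds,
                             hidden=cfg.classifier_hidden, seed=cfg.seed)
        aucs = [fm["auc"] for fm in model.fold_metrics if np.isfinite(fm["auc"])]
        classifier_auc[alg] = float(np.mean(aucs)) if aucs else float("nan")
        archive = enrol(zip(ids, labels.tolist(), X), algorithm=alg,
                        representation=cfg.representation)
        archive.classify(model)
        row = {}
        for arch in ("SA", "PA"):
            metrics = evaluate_retrieval(archive, architecture=arch,
                                         model=model if arch == "PA" else None,
                                         m_values=cfg.m_values, metric=cfg.metric)
            for m in cfg.m_values:
                row[f"{arch}_Pr@{m}"] = round(metrics.pr_at[m], 2)
            row[f"{arch}_A_GS"] = round(metrics.a_gs, 2)
        rows[alg] = row
        logger.info("%-6s SA A_GS %.2f | PA A_GS %.2f", alg,
                    row["SA_A_GS"], row["PA_A_GS"])

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["Mean"] = table.mean(axis=0).round(2)
    table.index.name = "algorithm"

    result = ExperimentResult(cfg, table, classifier_auc)
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"{cfg.region}_{cfg.representation}"
        table.to_csv(outdir / f"metrics_{tag}.csv")
        pd.Series(classifier_auc, name="cv_auc").to_csv(
            outdir / f"classifier_auc_{tag}.csv"
        )
        (outdir / f"config_{tag}.yaml").write_text(
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(cfg).items()})
        )
    return result
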