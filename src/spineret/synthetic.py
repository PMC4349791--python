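"""Synthetic vertebra shapes and x-ray-like renderings.

Every anterior-osteophyte (AO) irregularity class handled by the
retrieval system can be generated here as a labelled 9-APR landmark set
plus a noisy grayscale rendering, so the whole pipeline is exercisable
without clinical radiographs.

Cervical classes follow the Macnab morphology taxonomy (claw, traction,
claw-traction) crossed with a slight/moderate/severe grading plus the
normal class -- 10 classes.  Lumbar classes are normal plus an
osteophyte at the lower, upper, or both anterior corners (L-LHC, U-LHC,
B-LHC) -- 4 classes.

Geometry: the vertebral body is a convex quadrilateral with small
random corner jitter (so a shape model trained on it has variance to
learn).  A traction spur protrudes horizontally from the anterior
corner with length ``s * anterior-edge-length``; a claw spur has the
same length but its tip is bent 30 degrees toward the adjacent disk.
``s`` grows with severity grade.  These are measurable stand-ins for
the qualitative radiological descriptions and are configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .shapes import NinePointShape, canonical_contour

__all__ = [
    "AOClass",
    "SyntheticSpec",
    "Dataset",
    "cervical_classes",
    "lumbar_classes",
    "classes_for_region",
    "class_by_name",
    "sample_shape",
    "render_image",
    "make_dataset",
    "save_dataset",
]

MACNAB_TYPES = ("claw", "traction", "claw-traction")
SEVERITIES = ("slight", "moderate", "severe")
LUMBAR_CORNERS = ("L-LHC", "U-LHC", "B-LHC")

#: Spur length as a fraction of the anterior edge length, per severity.
SEVERITY_SCALES = {"slight": 0.05, "moderate": 0.12, "severe": 0.20}
#: Spur scale used for lumbar corner osteophytes (no severity grading).
LUMBAR_SPUR_SCALE = 0.15
#: Claw tips bend this many degrees from horizontal toward the disk.
CLAW_BEND_DEG = 30.0

BACKGROUND_INTENSITY = 0.25
FOREGROUND_INTENSITY = 0.75


@dataclass(frozen=True)
class AOClass:
    """One anterior-osteophyte irregularity class."""

    region: str  # cervical | lumbar
    label: str
    macnab: str = "none"  # none | claw | traction | claw-traction (cervical)
    severity: str = "none"  # none | slight | moderate | severe (cervical)
    corner: str = "none"  # none | L-LHC | U-LHC | B-LHC (lumbar)

    def __post_init__(self):
        if self.region not in ("cervical", "lumbar"):
            raise ValueError(f"unknown region {self.region!r}")
        if (self.severity == "none") != (self.macnab == "none"):
            raise ValueError("severity must be 'none' exactly when macnab is 'none'")


def cervical_classes() -> list[AOClass]:
    """The 10 cervical classes: normal plus 3 Macnab types x 3 severities."""
    classes = [AOClass("cervical", "normal")]
    for macnab in MACNAB_TYPES:
        for sev in SEVERITIES:
            classes.append(
                AOClass("cervical", f"{sev}-{macnab}", macnab=macnab, severity=sev)
            )
    return classes


def lumbar_classes() -> list[AOClass]:
    """The 4 lumbar classes: normal, L-LHC, U-LHC, B-LHC."""
    classes = [AOClass("lumbar", "normal")]
    for corner in LUMBAR_CORNERS:
        classes.append(AOClass("lumbar", corner, corner=corner))
    return classes


def classes_for_region(region: str) -> list[AOClass]:
    if region == "cervical":
        return cervical_classes()
    if region == "lumbar":
        return lumbar_classes()
    raise ValueError(f"unknown region {region!r}")


def class_by_name(region: str, label: str) -> AOClass:
    for c in classes_for_region(region):
        if c.label == label:
            return c
    names = [c.label for c in classes_for_region(region)]
    raise ValueError(f"unknown {region} class {label!r}; known: {names}")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    region: str = "cervical"
    per_class: int = 10
    image_size: int = 128
    noise_level: float = 0.05  # std of additive Gaussian noise, intensity units
    blur_sigma: float = 1.0  # px
    seed: int = 0

    def __post_init__(self):
        if self.region not in ("cervical", "lumbar"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.per_class < 0:
            raise ValueError("per-class count must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if self.image_size < 32:
            raise ValueError("image size must be >= 32 px")


@dataclass
class DatasetRecord:
    image_id: str
    ao_class: AOClass
    shape: NinePointShape
    image: np.ndarray


@dataclass
class Dataset:
    spec: SyntheticSpec
    records: list[DatasetRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.ao_class.label for r in self.records]


def _rotate(v: np.ndarray, degrees: float) -> np.ndarray:
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _spur(corner: np.ndarray, anterior: np.ndarray, toward_disk: np.ndarray,
          length: float, kind: str) -> np.ndarray:
    """Tip of a spur protruding from ``corner``.

    ``anterior`` is the outward unit normal of the anterior edge;
    ``toward_disk`` the unit direction toward the adjacent disk.
    A traction spur protrudes horizontally; a claw spur is bent 30
    degrees from the anterior direction toward the disk.
    """
    if kind == "traction":
        direction = anterior
    elif kind == "claw":
        c = np.cos(np.deg2rad(CLAW_BEND_DEG))
        s = np.sin(np.deg2rad(CLAW_BEND_DEG))
        direction = c * anterior + s * toward_disk
    else:
        raise ValueError(f"unknown spur kind {kind!r}")
    return corner + length * direction


def sample_shape(
    ao_class: AOClass,
    seed: int,
    severity_scale: float | None = None,
    image_size: int = 128,
) -> NinePointShape:
    """Draw one labelled 9-APR landmark configuration.

    The same seed produces the same base quadrilateral for every class
    (random draws happen in class-independent order), so spur length is
    the only severity-dependent quantity and severity monotonicity holds
    seed by seed.  ``severity_scale`` overrides the per-grade spur
    fraction.
    """
    if not isinstance(ao_class, AOClass):
        raise TypeError("ao_class must be an AOClass")
    rng = np.random.default_rng(seed)
    S = float(image_size)

    width = 0.42 * S
    height = 0.30 * S
    cx, cy = 0.56 * S, 0.50 * S
    xa, xp = cx - width / 2, cx + width / 2
    yt, yb = cy - height / 2, cy + height / 2

    jitter = rng.uniform(-0.03, 0.03, size=(6, 2)) * width
    p1 = np.array([xa, yb]) + jitter[0]  # lower anterior corner
    p3 = np.array([xp, yb]) + jitter[1]  # lower posterior corner
    p4 = np.array([xp, yt]) + jitter[2]  # upper posterior corner
    p6 = np.array([xa, yt]) + jitter[3]  # upper anterior corner
    p2 = (p1 + p3) / 2 + jitter[4] * 0.5  # lower edge midpoint
    p5 = (p4 + p6) / 2 + jitter[5] * 0.5  # upper edge midpoint
    p8 = (p6 + p1) / 2  # anterior midpoint

    # outward normal of the anterior edge (points away from the body)
    edge = p1 - p6
    normal = np.array([-edge[1], edge[0]])
    normal /= np.linalg.norm(normal)
    if normal[0] > 0:  # anterior side is the low-x side
        normal = -normal
    up = np.array([0.0, -1.0])
    down = np.array([0.0, 1.0])
    edge_len = float(np.linalg.norm(edge))

    p7 = p6.copy()  # upper AO point
    p9 = p1.copy()  # lower AO point

    if ao_class.region == "cervical" and ao_class.macnab != "none":
        s = SEVERITY_SCALES[ao_class.severity] if severity_scale is None else severity_scale
        length = s * edge_len
        if ao_class.macnab == "claw":
            p7 = _spur(p6, normal, up, length, "claw")
        elif ao_class.macnab == "traction":
            p7 = _spur(p6, normal, up, length, "traction")
        else:  # claw-traction: both features
            p7 = _spur(p6, normal, up, length, "claw")
            p9 = _spur(p1, normal, down, length, "traction")
    elif ao_class.region == "lumbar" and ao_class.corner != "none":
        s = LUMBAR_SPUR_SCALE if severity_scale is None else severity_scale
        length = s * edge_len
        if ao_class.corner in ("U-LHC", "B-LHC"):
            p7 = _spur(p6, normal, up, length, "traction")
        if ao_class.corner in ("L-LHC", "B-LHC"):
            p9 = _spur(p1, normal, down, length, "traction")

    pts = np.array([p1, p2, p3, p4, p5, p6, p7, p8, p9])
    return NinePointShape(pts, region=ao_class.region, label=ao_class.label)


def spur_protrusion(shape: NinePointShape, which: str = "upper") -> float:
    """Signed anterior displacement of an AO point beyond the 1-6 edge.

    Distance from landmark 7 (``upper``) or 9 (``lower``) to the line
    through landmarks 1 and 6, measured along the outward normal.
    """
    p1, p6 = shape.point(1), shape.point(6)
    edge = p1 - p6
    normal = np.array([-edge[1], edge[0]])
    normal /= np.linalg.norm(normal)
    if normal[0] > 0:
        normal = -normal
    p = shape.point(7) if which == "upper" else shape.point(9)
    return float(np.dot(p - p6, normal))


def render_image(
    shape: NinePointShape, spec: SyntheticSpec, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a shape into a noisy grayscale image.

    The polygon interior is drawn at 0.75 on a 0.25 background, smoothed
    by ``spec.blur_sigma`` and corrupted with additive Gaussian noise of
    std ``spec.noise_level``; intensities are clipped to [0, 1].
    Returns ``(image, landmarks)`` with the ground-truth landmarks
    passed through unchanged.
    """
    size = spec.image_size
    pts = shape.points
    margin = 5.0
    if (pts.min() < margin) or (pts.max() > size - 1 - margin):
        raise ValueError("shape does not fit within image bounds with 5 px margin")

    img = np.full((size, size), BACKGROUND_INTENSITY, dtype=float)
    poly = canonical_contour(shape).points
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(size, size))
    img[rr, cc] = FOREGROUND_INTENSITY
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        img = img + rng.normal(0.0, spec.noise_level, img.shape)
    return np.clip(img, 0.0, 1.0), pts.copy()


def _place(shape: NinePointShape, rng: np.random.Generator, size: int) -> NinePointShape:
    """Apply a small random similarity transform (pose variation)."""
    pts = shape.points
    center = pts.mean(axis=0)
    angle = np.deg2rad(rng.uniform(-6.0, 6.0))
    scale = rng.uniform(0.92, 1.08)
    shift = rng.uniform(-3.0, 3.0, size=2)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    new = (pts - center) @ rot.T * scale + center + shift
    lo, hi = 5.5, size - 6.5
    new = np.clip(new, lo, hi)  # conservative: keep the 5 px render margin
    return NinePointShape(new, region=shape.region, label=shape.label)


def make_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate a labelled synthetic dataset (images + landmarks).

    Per-class counts match ``spec.per_class`` exactly; every image gets
    its own child seed derived from ``spec.seed`` so regeneration with
    the same spec is bit-identical.
    """
    classes = classes_for_region(spec.region)
    if spec.per_class * len(classes) == 0:
        raise ValueError("dataset would be empty (per_class == 0)")
    ds = Dataset(spec=spec)
    for ci, ao in enumerate(classes):
        for i in range(spec.per_class):
            child = np.random.SeedSequence([spec.seed, ci, i])
            shape_seed, place_seed, noise_seed = (
                int(x) for x in child.generate_state(3) % (2**31)
            )
            shape = sample_shape(ao, seed=shape_seed, image_size=spec.image_size)
            shape = _place(shape, np.random.default_rng(place_seed), spec.image_size)
            img, pts = render_image(shape, spec, seed=noise_seed)
            ds.records.append(
                DatasetRecord(
                    image_id=f"{spec.region}_{ao.label}_{i:03d}",
                    ao_class=ao,
                    shape=shape,
                    image=img,
                )
            )
    return ds


def save_dataset(ds: Dataset, outdir: str | Path) -> dict:
    """Write a dataset to disk and return its manifest.

    Layout: 8-bit grayscale PNGs, one ``annotations.csv`` with columns
    image_id, region, class, x1, y1, ..., x9, y9 (0-based pixel
    coordinates), and a ``manifest.json`` listing every file with its
    class label.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    entries = []
    for rec in ds.records:
        fname = f"{rec.image_id}.png"
        arr = np.round(rec.image * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(outdir / fname)
        row = {"image_id": rec.image_id, "region": rec.ao_class.region,
               "class": rec.ao_class.label}
        for j, (x, y) in enumerate(rec.shape.points, start=1):
            row[f"x{j}"] = x
            row[f"y{j}"] = y
        rows.append(row)
        entries.append({"file": fname, "image_id": rec.image_id,
                        "class": rec.ao_class.label, "representation": "9-APR"})
    pd.DataFrame(rows).to_csv(outdir / "annotations.csv", index=False)
    manifest = {
        "format_version": 1,
        "spec": asdict(ds.spec),
        "n_images": len(ds),
        "images": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_dataset(indir: str | Path) -> Dataset:
    """Read a dataset written by :func:`save_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    spec = SyntheticSpec(**manifest["spec"])
    ann = pd.read_csv(indir / "annotations.csv")
    ds = Dataset(spec=spec)
    by_id = {e["image_id"]: e["file"] for e in manifest["images"]}
    for _, row in ann.iterrows():
        img = np.asarray(Image.open(indir / by_id[row["image_id"]]), dtype=float) / 255.0
        pts = np.array([[row[f"x{j}"], row[f"y{j}"]] for j in range(1, 10)])
        ao = class_by_name(row["region"], row["class"])
        shape = NinePointShape(pts, region=row["region"], label=row["class"])
        ds.records.append(DatasetRecord(row["image_id"], ao, shape, img))
    return ds


def dataset_digest(indir: str | Path) -> str:
    """SHA-256 over all dataset files (manifest, annotations, images)."""
    indir = Path(indir)
    h = hashlib.sha256()
    for f in sorted(indir.iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()
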