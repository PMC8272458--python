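"""Object segmentation and well-level feature aggregation.

Each fluorescent object (a colony or debris particle) yields eleven
measurements: six shape parameters (area, circumference, diameter,
circularity, anisometry, compactness) and five intensity statistics over its
pixels (mean, median, total, maximum, minimum).  A well pools the objects of
all its imaged fields and is summarised by a fixed 112-feature catalog:

* 11 object measures x 9 across-object statistics
  {mean, median, sum, sd, cv, min, max, p10, p90}            -> 99 features
* covariance of each shape measure with per-object mean intensity -> 6
* 7 well scalars: object count, foreground area fraction, total foreground
  intensity, background mean, background SD, mean nearest-neighbour centroid
  distance, fraction of objects brighter than background mean + 3 SD.

The instrument software behind the original screen does not publish its
feature list; this catalog is a documented reconstruction constrained to the
named measure families and the total of 112, and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import measure
from skimage.filters import threshold_otsu

from .plate_model import WellAddress

#: Per-object measures, in catalog order. The first six are shape parameters.
OBJECT_MEASURES = (
    "area",
    "circumference",
    "diameter",
    "circularity",
    "anisometry",
    "compactness",
    "intensity_mean",
    "intensity_median",
    "intensity_total",
    "intensity_max",
    "intensity_min",
)
SHAPE_MEASURES = OBJECT_MEASURES[:6]

#: Across-object statistics applied to every measure.
AGGREGATE_STATS = ("mean", "median", "sum", "sd", "cv", "min", "max", "p10", "p90")

#: Whole-well scalar features.
WELL_SCALARS = (
    "object_count",
    "foreground_area_fraction",
    "total_foreground_intensity",
    "background_mean",
    "background_sd",
    "nn_distance_mean",
    "bright_object_fraction",
)

# Rasterization can push 4*pi*A/P^2 slightly above 1 for small objects.
CIRCULARITY_CAP = 1.1


def default_catalog() -> tuple[str, ...]:
    """The fixed, ordered 112-feature catalog."""
    names = [f"{m}_{s}" for m in OBJECT_MEASURES for s in AGGREGATE_STATS]
    names += [f"cov_{m}_intensity_mean" for m in SHAPE_MEASURES]
    names += list(WELL_SCALARS)
    return tuple(names)


class SegmentationError(ValueError):
    """Raised for images that cannot be segmented (empty, wrong ndim)."""


def segment_objects(
    image: np.ndarray,
    threshold_method: str = "otsu",
    min_object_area: int = 10,
) -> np.ndarray:
    """Label connected fluorescent objects in a grayscale field image.

    Otsu's threshold separates foreground from background; connected
    components smaller than ``min_object_area`` pixels are discarded.  A
    robust guard declares the field object-free when the Otsu threshold does
    not clear the background level (median + 3 robust SD) — on a pure-noise
    image Otsu would otherwise bisect the noise distribution.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise SegmentationError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if threshold_method != "otsu":
        raise SegmentationError(f"unknown threshold method {threshold_method!r}")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)

    thr = threshold_otsu(img)
    med = np.median(img)
    robust_sd = 1.4826 * np.median(np.abs(img - med))
    if thr <= med + 3.0 * robust_sd:
        return np.zeros(img.shape, dtype=np.int32)

    mask = img > thr
    lab = measure.label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_object_area
    keep[0] = False
    return measure.label(keep[lab], connectivity=2).astype(np.int32)


@dataclass
class WellObjectTable:
    """Pooled per-object measurements for one well.

    ``objects`` has one row per object with the eleven measure columns plus
    ``label``, ``field``, ``centroid_r`` and ``centroid_c``; background
    statistics are pooled over the non-object pixels of all fields.
    """

    well: WellAddress | None
    objects: pd.DataFrame
    n_fields: int
    image_area: int
    background_mean: float
    background_sd: float
    background_n: int

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def _intensity_median(mask: np.ndarray, intensity: np.ndarray) -> float:
    return float(np.median(intensity[mask]))


def _intensity_total(mask: np.ndarray, intensity: np.ndarray) -> float:
    return float(np.sum(intensity[mask]))


def compute_object_features(
    labels: np.ndarray, image: np.ndarray, field: int = 0
) -> WellObjectTable:
    """Per-object shape and intensity measurements for one labeled field.

    circularity = 4*pi*area / perimeter^2 (capped at 1.1 for rasterization),
    anisometry = major / minor axis of the second-moment ellipse,
    compactness = area / convex-hull area (solidity),
    diameter = equivalent-circle diameter 2*sqrt(area/pi).
    """
    labels = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if labels.shape != img.shape:
        raise ValueError(f"mask shape {labels.shape} != image shape {img.shape}")

    bg = img[labels == 0]
    bg_mean = float(bg.mean()) if bg.size else 0.0
    bg_sd = float(bg.std(ddof=1)) if bg.size > 1 else 0.0

    if labels.max() == 0:
        objects = pd.DataFrame(
            columns=["label", "field", *OBJECT_MEASURES, "centroid_r", "centroid_c"]
        )
    else:
        props = measure.regionprops_table(
            labels,
            intensity_image=img,
            properties=(
                "label",
                "area",
                "perimeter",
                "axis_major_length",
                "axis_minor_length",
                "solidity",
                "centroid",
                "intensity_mean",
                "intensity_max",
                "intensity_min",
            ),
            extra_properties=(_intensity_median, _intensity_total),
        )
        t = pd.DataFrame(props)
        area = t["area"].to_numpy(float)
        perim = np.maximum(t["perimeter"].to_numpy(float), 1.0)
        minor = np.maximum(t["axis_minor_length"].to_numpy(float), 0.5)
        objects = pd.DataFrame(
            {
                "label": t["label"].to_numpy(int),
                "field": field,
                "area": area,
                "circumference": perim,
                "diameter": 2.0 * np.sqrt(area / np.pi),
                "circularity": np.minimum(4.0 * np.pi * area / perim**2, CIRCULARITY_CAP),
                "anisometry": t["axis_major_length"].to_numpy(float) / minor,
                "compactness": t["solidity"].to_numpy(float),
                "intensity_mean": t["intensity_mean"].to_numpy(float),
                "intensity_median": t["_intensity_median"].to_numpy(float),
                "intensity_total": t["_intensity_total"].to_numpy(float),
                "intensity_max": t["intensity_max"].to_numpy(float),
                "intensity_min": t["intensity_min"].to_numpy(float),
                "centroid_r": t["centroid-0"].to_numpy(float),
                "centroid_c": t["centroid-1"].to_numpy(float),
            }
        )

    return WellObjectTable(
        well=None,
        objects=objects,
        n_fields=1,
        image_area=int(img.size),
        background_mean=bg_mean,
        background_sd=bg_sd,
        background_n=int(bg.size),
    )


def pool_well_fields(
    tables: list[WellObjectTable], well: WellAddress | None = None
) -> WellObjectTable:
    """Pool the objects of all fields of one well into a single table.

    Object labels are renumbered to stay unique across fields; background
    statistics are combined over all fields' background pixels.
    """
    if not tables:
        raise ValueError("no field tables to pool")
    frames = []
    offset = 0
    for i, t in enumerate(tables):
        obj = t.objects.copy()
        if len(obj):
            obj["label"] = np.arange(offset + 1, offset + 1 + len(obj))
            obj["field"] = i
            offset += len(obj)
        frames.append(obj)
    pooled = pd.concat(frames, ignore_index=True) if frames else tables[0].objects

    ns = np.array([t.background_n for t in tables], dtype=float)
    means = np.array([t.background_mean for t in tables])
    sds = np.array([t.background_sd for t in tables])
    n_tot = ns.sum()
    if n_tot > 0:
        grand = float(np.sum(ns * means) / n_tot)
        # pooled variance: within-field + between-field components
        ss = np.sum((ns - 1).clip(min=0) * sds**2) + np.sum(ns * (means - grand) ** 2)
        sd = float(np.sqrt(ss / (n_tot - 1))) if n_tot > 1 else 0.0
    else:
        grand, sd = 0.0, 0.0

    return WellObjectTable(
        well=well,
        objects=pooled,
        n_fields=len(tables),
        image_area=int(sum(t.image_area for t in tables)),
        background_mean=grand,
        background_sd=sd,
        background_n=int(n_tot),
    )


@dataclass
class WellFeatureVector:
    """Ordered, named well-level feature values (length 112 by default)."""

    well: WellAddress | None
    names: tuple[str, ...]
    values: np.ndarray
    no_object_flag: bool

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=str(self.well))


def _stat(values: np.ndarray, stat: str) -> float:
    n = values.size
    if stat == "mean":
        return float(values.mean())
    if stat == "median":
        return float(np.median(values))
    if stat == "sum":
        return float(values.sum())
    if stat == "sd":
        return float(values.std(ddof=1)) if n > 1 else 0.0
    if stat == "cv":
        if n < 2:
            return 0.0
        m = values.mean()
        return float(values.std(ddof=1) / m) if m != 0 else 0.0
    if stat == "min":
        return float(values.min())
    if stat == "max":
        return float(values.max())
    if stat == "p10":
        return float(np.percentile(values, 10))
    if stat == "p90":
        return float(np.percentile(values, 90))
    raise KeyError(stat)


def _nn_distance_mean(objects: pd.DataFrame) -> float:
    # centroids of different fields live in different coordinate frames:
    # nearest neighbours are computed within each field, then averaged.
    dists = []
    for _, grp in objects.groupby("field"):
        if len(grp) < 2:
            continue
        pts = grp[["centroid_r", "centroid_c"]].to_numpy(float)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        dists.append(d.min(axis=1))
    if not dists:
        return 0.0
    return float(np.concatenate(dists).mean())


def aggregate_well_features(
    table: WellObjectTable, catalog: tuple[str, ...] | None = None
) -> WellFeatureVector:
    """Collapse a well's object table into its feature vector.

    A well with no segmented objects (e.g. complete cell death) keeps a
    vector of zeros with ``no_object_flag`` set, so it remains scoreable
    rather than dropping out of the analysis.
    """
    names = tuple(catalog) if catalog is not None else default_catalog()
    obj = table.objects
    if len(obj) == 0:
        return WellFeatureVector(
            well=table.well,
            names=names,
            values=np.zeros(len(names)),
            no_object_flag=True,
        )

    computed: dict[str, float] = {}
    for m in OBJECT_MEASURES:
        col = obj[m].to_numpy(float)
        for s in AGGREGATE_STATS:
            computed[f"{m}_{s}"] = _stat(col, s)
    imean = obj["intensity_mean"].to_numpy(float)
    for m in SHAPE_MEASURES:
        col = obj[m].to_numpy(float)
        computed[f"cov_{m}_intensity_mean"] = (
            float(np.cov(col, imean, ddof=1)[0, 1]) if len(obj) > 1 else 0.0
        )
    computed["object_count"] = float(len(obj))
    computed["foreground_area_fraction"] = (
        float(obj["area"].sum() / table.image_area) if table.image_area else 0.0
    )
    computed["total_foreground_intensity"] = float(obj["intensity_total"].sum())
    computed["background_mean"] = table.background_mean
    computed["background_sd"] = table.background_sd
    computed["nn_distance_mean"] = _nn_distance_mean(obj)
    bright_cut = table.background_mean + 3.0 * table.background_sd
    computed["bright_object_fraction"] = float((imean > bright_cut).mean())

    try:
        values = np.array([computed[n] for n in names], dtype=float)
    except KeyError as e:
        raise KeyError(f"unknown feature name in catalog: {e.args[0]!r}") from None
    return WellFeatureVector(
        well=table.well, names=names, values=values, no_object_flag=False
    )


def extract_well_features(
    images: list[np.ndarray],
    well: WellAddress | None = None,
    threshold_method: str = "otsu",
    min_object_area: int = 10,
    catalog: tuple[str, ...] | None = None,
) -> WellFeatureVector:
    """Segment and aggregate all field images of one well."""
    tables = []
    for i, img in enumerate(images):
        labels = segment_objects(img, threshold_method, min_object_area)
        tables.append(compute_object_features(labels, img, field=i))
    return aggregate_well_features(pool_well_fields(tables, well=well), catalog)


def features_dataframe(vectors: list[WellFeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a wells x features table (plus flag column)."""
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].names
    rows = []
    for v in vectors:
        if v.names != names:
            raise ValueError("feature vectors use different catalogs")
        rows.append([str(v.well), *v.values, v.no_object_flag])
    return pd.DataFrame(rows, columns=["well", *names, "no_objects"])
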