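"""Seeded synthetic high-content screen generator.

Two complementary paths produce test data with the statistical structure the
multi-parametric analysis assumes:

* an **image path** that renders per-well 16-bit fluorescence fields —
  active-control (AC, +DOX) wells carry many compact bright colonies,
  negative-control (NC, -DOX) wells sparse small dim debris, compound wells
  a mixture with a small planted-active fraction;
* a **feature-space fast path** that draws the 112-dimensional well feature
  vectors directly from multivariate normal control populations, bypassing
  rendering and segmentation for screen-scale simulations.

Duplicate plates share one ground-truth assignment (a planted active is
active in both replicates) but receive independent measurement noise, which
is exactly the structure the duplicate-run hit rule relies on.

In the feature-space model, features are standardized (NC mean 0, SD 1).
Twelve strongly separating features (colony count / size / brightness
summaries) sit ``control_separation`` SDs apart between AC and NC wells and
are mutually correlated; twenty-four moderately responding features move by
``moderate_effect`` times that; the remainder is uninformative noise.  The
default ``control_separation`` is calibrated once so that the default
synthetic screen lands in a plate-QC band of Z' ~ 0.6, matching the
performance of a well-behaved real screen; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image_features import default_catalog
from .plate_model import (
    N_COLUMNS,
    ROWS,
    PlateLayout,
    WellAddress,
    WellEntry,
    WellRole,
    write_plate_map,
)

__all__ = [
    "PhenotypeParams",
    "ScreenSimConfig",
    "AC_PHENOTYPE",
    "NC_PHENOTYPE",
    "ObjectTruth",
    "FeatureSpaceModel",
    "ScreenSimResult",
    "default_screen_layout",
    "simulate_well_image",
    "feature_space_model",
    "simulate_feature_table",
    "simulate_feature_screen",
    "simulate_screen",
]


@dataclass(frozen=True)
class PhenotypeParams:
    """Rendering parameters of one well phenotype.

    ``objects_per_well`` is a Poisson mean; colony radii are log-normal in
    pixels; ``intensity_mean``/``intensity_sd`` describe peak foreground
    fluorescence in camera units (absolute, i.e. including the background
    pedestal); eccentricity controls blob elongation.
    """

    objects_per_well: float
    radius_log_mean: float
    radius_log_sd: float
    intensity_mean: float
    intensity_sd: float
    eccentricity_mean: float
    background_mean: float
    background_sd: float

    def __post_init__(self) -> None:
        for f in (
            "objects_per_well",
            "radius_log_sd",
            "intensity_sd",
            "background_mean",
            "background_sd",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if not 0.0 <= self.eccentricity_mean < 1.0:
            raise ValueError("eccentricity_mean must lie in [0, 1)")


#: +DOX wells: many compact, bright, dome-like colonies.
AC_PHENOTYPE = PhenotypeParams(
    objects_per_well=25.0,
    radius_log_mean=math.log(9.0),
    radius_log_sd=0.25,
    intensity_mean=3200.0,
    intensity_sd=500.0,
    eccentricity_mean=0.2,
    background_mean=400.0,
    background_sd=25.0,
)

#: -DOX wells: sparse, small, dim debris after reporter loss and collapse.
NC_PHENOTYPE = PhenotypeParams(
    objects_per_well=4.0,
    radius_log_mean=math.log(3.5),
    radius_log_sd=0.3,
    intensity_mean=900.0,
    intensity_sd=200.0,
    eccentricity_mean=0.45,
    background_mean=400.0,
    background_sd=25.0,
)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the synthetic screen (all defaults documented)."""

    ac_params: PhenotypeParams = AC_PHENOTYPE
    nc_params: PhenotypeParams = NC_PHENOTYPE
    active_fraction: float = 0.05
    active_effect: float = 1.0
    dimmer_active_fraction: float = 0.25
    image_size: int = 256
    fields_per_well: int = 4
    seed: int = 0
    # feature-space fast-path parameters (standardized units)
    control_separation: float = 11.0  # calibrated; see module docstring
    moderate_effect: float = 0.3
    strong_corr: float = 0.5
    moderate_corr: float = 0.3

    def __post_init__(self) -> None:
        for f in ("active_fraction", "active_effect", "dimmer_active_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1]")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenSimConfig":
        d = dict(d)
        for key in ("ac_params", "nc_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = PhenotypeParams(**d[key])
        return cls(**d)


def default_screen_layout(
    plate_id: str = "plate1",
    replicate_id: int = 1,
    concentration_um: float = 5.0,
    compound_prefix: str = "C",
) -> PlateLayout:
    """The default screening layout: outer control columns, 320 compounds.

    Columns 1 and 23 are active controls, columns 2 and 24 negative controls
    (32 wells each); columns 3-22 hold compounds ``C0001``..``C0320`` in
    row-major order.
    """
    wells: dict[WellAddress, WellEntry] = {}
    k = 0
    for row in ROWS:
        for col in range(1, N_COLUMNS + 1):
            addr = WellAddress(row, col)
            if col in (1, 23):
                wells[addr] = WellEntry(role=WellRole.ACTIVE_CONTROL)
            elif col in (2, 24):
                wells[addr] = WellEntry(role=WellRole.NEGATIVE_CONTROL)
            else:
                k += 1
                wells[addr] = WellEntry(
                    role=WellRole.COMPOUND,
                    compound_id=f"{compound_prefix}{k:04d}",
                    concentration_um=concentration_um,
                )
    return PlateLayout(plate_id=plate_id, replicate_id=replicate_id, wells=wells)


# --------------------------------------------------------------------------
# image path
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectTruth:
    """Ground truth of one rendered blob."""

    center_r: float
    center_c: float
    sigma_major: float
    sigma_minor: float
    theta: float
    amplitude: float  # peak height above the background pedestal

    @property
    def integrated_intensity(self) -> float:
        """Analytic integral of the blob over the plane (noise-free)."""
        return float(self.amplitude * 2.0 * math.pi * self.sigma_major * self.sigma_minor)


def simulate_well_image(
    params: PhenotypeParams,
    image_size: int = 256,
    seed: int | np.random.Generator | None = None,
    n_objects: int | None = None,
    non_overlapping: bool = True,
    return_truth: bool = False,
):
    """Render one 16-bit grayscale field image of a well phenotype.

    Objects are additive smooth blobs — anisotropic 2-D Gaussian profiles
    with random orientation — over Gaussian background noise, clipped to the
    16-bit dynamic range.  Bit-identical for identical ``(params, seed)``.
    With ``non_overlapping`` (default) object centers are rejection-sampled
    to keep blobs separated; if a placement cannot be found after 100
    attempts the object is placed anyway (dense wells may overlap).
    """
    if image_size <= 0:
        raise ValueError(f"non-positive image size {image_size}")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(params.objects_per_well)) if n_objects is None else int(n_objects)

    truths: list[ObjectTruth] = []
    # draw object geometry/photometry first, then placement, then noise
    geom = []
    for _ in range(n):
        radius = float(np.exp(rng.normal(params.radius_log_mean, params.radius_log_sd)))
        sigma = max(radius / 2.0, 0.6)
        ecc = float(np.clip(rng.normal(params.eccentricity_mean, 0.1), 0.0, 0.9))
        stretch = (1.0 - ecc**2) ** 0.25
        theta = float(rng.uniform(0.0, math.pi))
        amplitude = max(
            float(rng.normal(params.intensity_mean, params.intensity_sd))
            - params.background_mean,
            0.05 * max(params.intensity_mean, 1.0),
        )
        geom.append((sigma / stretch, sigma * stretch, theta, amplitude))

    centers: list[tuple[float, float]] = []
    for sa, sb, _, _ in geom:
        margin = min(2.0 * sa, image_size / 2.0 - 1.0)
        lo, hi = margin, image_size - margin
        placed = None
        for _ in range(100):
            r, c = rng.uniform(lo, hi), rng.uniform(lo, hi)
            if not non_overlapping:
                placed = (r, c)
                break
            ok = True
            for (pr, pc), (psa, _, _, _) in zip(centers, geom):
                if (r - pr) ** 2 + (c - pc) ** 2 < (2.5 * (sa + psa) + 2.0) ** 2:
                    ok = False
                    break
            if ok:
                placed = (r, c)
                break
        if placed is None:  # crowded well: accept the last overlap
            placed = (r, c)
        centers.append(placed)

    img = params.background_mean + rng.normal(
        0.0, params.background_sd, size=(image_size, image_size)
    )
    for (r0, c0), (sa, sb, theta, amp) in zip(centers, geom):
        truths.append(
            ObjectTruth(
                center_r=r0, center_c=c0, sigma_major=sa, sigma_minor=sb,
                theta=theta, amplitude=amp,
            )
        )
        half = int(math.ceil(4.0 * sa)) + 1
        r_lo, r_hi = max(int(r0) - half, 0), min(int(r0) + half + 1, image_size)
        c_lo, c_hi = max(int(c0) - half, 0), min(int(c0) + half + 1, image_size)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dr, dc = rr - r0, cc - c0
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
            -0.5 * ((u / sa) ** 2 + (v / sb) ** 2)
        )

    out = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return (out, truths) if return_truth else out


def _interpolate_params(
    nc: PhenotypeParams, ac: PhenotypeParams, t: float
) -> PhenotypeParams:
    """Linear interpolation of every phenotype parameter from NC toward AC."""
    fields = {
        f.name: (1.0 - t) * getattr(nc, f.name) + t * getattr(ac, f.name)
        for f in dataclasses.fields(PhenotypeParams)
    }
    return PhenotypeParams(**fields)


def _dimmer_variant(params: PhenotypeParams) -> PhenotypeParams:
    """Enlarged-but-dimmer active phenotype (bigger colonies, weaker reporter)."""
    dim_intensity = params.background_mean + 0.6 * (
        params.intensity_mean - params.background_mean
    )
    return dataclasses.replace(
        params,
        radius_log_mean=params.radius_log_mean + math.log(1.15),
        intensity_mean=dim_intensity,
    )


# --------------------------------------------------------------------------
# feature-space fast path
# --------------------------------------------------------------------------

#: Features that separate the AC and NC phenotypes strongly (colony count,
#: size and brightness summaries).  The first eight track colony size and
#: shape, the last four fluorescence intensity.
STRONG_SIZE_FEATURES = (
    "object_count",
    "area_mean",
    "area_median",
    "area_sum",
    "diameter_mean",
    "foreground_area_fraction",
    "circularity_mean",
    "compactness_mean",
)
STRONG_INTENSITY_FEATURES = (
    "intensity_mean_mean",
    "intensity_total_sum",
    "intensity_max_mean",
    "total_foreground_intensity",
)
STRONG_FEATURES = STRONG_SIZE_FEATURES + STRONG_INTENSITY_FEATURES

MODERATE_FEATURES = (
    "area_p90", "area_p10", "area_min", "area_max",
    "diameter_median", "diameter_sum", "diameter_p90",
    "circumference_mean", "circumference_median", "circumference_sum",
    "intensity_mean_median", "intensity_mean_p90",
    "intensity_median_mean", "intensity_median_median",
    "intensity_total_mean", "intensity_max_max", "intensity_min_mean",
    "bright_object_fraction", "nn_distance_mean",
    "cov_area_intensity_mean", "cov_diameter_intensity_mean",
    "circularity_median", "compactness_median", "anisometry_mean",
)


@dataclass(frozen=True)
class FeatureSpaceModel:
    """Population parameters behind the feature-space simulator.

    Recorded explicitly so parameter-recovery tests can compare estimates
    against the generating truth.
    """

    names: tuple[str, ...]
    mu_ac: np.ndarray
    mu_nc: np.ndarray
    cov: np.ndarray  # shared AC/NC covariance (standardized scale)
    strong: tuple[str, ...]
    moderate: tuple[str, ...]

    @property
    def chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov)


def feature_space_model(
    config: ScreenSimConfig, feature_dim: int | None = None
) -> FeatureSpaceModel:
    """Build the multivariate-normal control populations for the fast path.

    With ``feature_dim=None`` the full 112-feature catalog is used and the
    strong/moderate sets are the documented name lists; with an integer
    dimension, generic names ``f000..`` are generated and the first features
    take the strong (then moderate) roles.
    """
    if feature_dim is None:
        names = default_catalog()
        strong = tuple(n for n in STRONG_FEATURES if n in names)
        moderate = tuple(n for n in MODERATE_FEATURES if n in names)
        strong_intensity = STRONG_INTENSITY_FEATURES
    else:
        if feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        names = tuple(f"f{i:03d}" for i in range(feature_dim))
        n_strong = min(12, feature_dim)
        strong = names[:n_strong]
        moderate = names[n_strong : n_strong + min(24, feature_dim - n_strong)]
        strong_intensity = strong[2 * len(strong) // 3 :]
    del strong_intensity  # the split only matters when drawing dim actives

    idx = {n: i for i, n in enumerate(names)}
    d = len(names)
    mu_nc = np.zeros(d)
    mu_ac = np.zeros(d)
    for n in strong:
        mu_ac[idx[n]] = config.control_separation
    for n in moderate:
        mu_ac[idx[n]] = config.moderate_effect * config.control_separation

    cov = np.eye(d)
    for block, rho in ((strong, config.strong_corr), (moderate, config.moderate_corr)):
        ii = [idx[n] for n in block]
        for a in ii:
            for b in ii:
                if a != b:
                    cov[a, b] = rho
    # compound-symmetry blocks with rho < 1 are positive definite
    return FeatureSpaceModel(
        names=names, mu_ac=mu_ac, mu_nc=mu_nc, cov=cov,
        strong=tuple(strong), moderate=tuple(moderate),
    )


def _draw_truth(
    compound_ids: list[str],
    wells: list[str],
    config: ScreenSimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One row per compound well: is_active flag and phenotype label."""
    active = rng.random(len(compound_ids)) < config.active_fraction
    dim = rng.random(len(compound_ids)) < config.dimmer_active_fraction
    phenotype = np.where(
        active, np.where(dim, "active_dim", "active"), "inactive"
    )
    return pd.DataFrame(
        {
            "compound_id": compound_ids,
            "well": wells,
            "is_active": active,
            "phenotype": phenotype,
        }
    )


def _active_mean(
    model: FeatureSpaceModel, config: ScreenSimConfig, dim: bool
) -> np.ndarray:
    """Mean vector of a planted active (NC moved toward AC by active_effect)."""
    delta = (model.mu_ac - model.mu_nc).copy()
    if dim:
        idx = {n: i for i, n in enumerate(model.names)}
        n_size = max(1, 2 * len(model.strong) // 3)
        for j, n in enumerate(model.strong):
            if n in STRONG_SIZE_FEATURES or (n not in STRONG_FEATURES and j < n_size):
                delta[idx[n]] *= 1.1  # enlarged colonies
            else:
                delta[idx[n]] *= 0.6  # dimmer reporter
    return model.mu_nc + config.active_effect * delta


def simulate_feature_table(
    config: ScreenSimConfig,
    n_ac: int = 32,
    n_nc: int = 32,
    n_compound: int = 320,
    feature_dim: int | None = None,
    seed: int | np.random.Generator | None = None,
    truth: pd.DataFrame | None = None,
    layout: PlateLayout | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one plate's well-by-feature table directly in feature space.

    Returns ``(features, truth)``: the features table has ``well``, ``role``
    and ``compound_id`` columns followed by the feature columns; the truth
    table records each compound well's planted phenotype.  Passing the truth
    table of a previous replicate reuses its assignment (shared truth,
    independent noise).  Fully deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    model = feature_space_model(config, feature_dim)

    if layout is not None:
        ac_wells = [str(a) for a in layout.addresses_with_role(WellRole.ACTIVE_CONTROL)]
        nc_wells = [str(a) for a in layout.addresses_with_role(WellRole.NEGATIVE_CONTROL)]
        comp = [
            (str(a), layout.wells[a].compound_id)
            for a in layout.addresses_with_role(WellRole.COMPOUND)
        ]
        comp_wells = [w for w, _ in comp]
        compound_ids = [c for _, c in comp]
    else:
        ac_wells = [f"AC{i:03d}" for i in range(n_ac)]
        nc_wells = [f"NC{i:03d}" for i in range(n_nc)]
        comp_wells = [f"CW{i:03d}" for i in range(n_compound)]
        compound_ids = [f"C{i + 1:04d}" for i in range(n_compound)]

    if truth is None:
        truth = _draw_truth(compound_ids, comp_wells, config, rng)
    else:
        missing = set(compound_ids) - set(truth["compound_id"])
        if missing:
            raise ValueError(f"truth table lacks compounds, e.g. {sorted(missing)[0]}")

    pheno = truth.set_index("compound_id")["phenotype"]
    rows_meta = (
        [(w, WellRole.ACTIVE_CONTROL.value, None) for w in ac_wells]
        + [(w, WellRole.NEGATIVE_CONTROL.value, None) for w in nc_wells]
        + [(w, WellRole.COMPOUND.value, c) for w, c in zip(comp_wells, compound_ids)]
    )
    mean_active = _active_mean(model, config, dim=False)
    mean_active_dim = _active_mean(model, config, dim=True)
    mu_rows = np.empty((len(rows_meta), len(model.names)))
    for i, (_, role, cid) in enumerate(rows_meta):
        if role == WellRole.ACTIVE_CONTROL.value:
            mu_rows[i] = model.mu_ac
        elif role == WellRole.NEGATIVE_CONTROL.value:
            mu_rows[i] = model.mu_nc
        else:
            label = pheno[cid]
            if label == "active":
                mu_rows[i] = mean_active
            elif label == "active_dim":
                mu_rows[i] = mean_active_dim
            else:
                mu_rows[i] = model.mu_nc

    Z = rng.standard_normal((len(rows_meta), len(model.names)))
    X = mu_rows + Z @ model.chol.T

    df = pd.DataFrame(
        {
            "well": [w for w, _, _ in rows_meta],
            "role": [r for _, r, _ in rows_meta],
            "compound_id": [c for _, _, c in rows_meta],
        }
    )
    df = pd.concat([df, pd.DataFrame(X, columns=list(model.names))], axis=1)
    return df, truth


def simulate_feature_screen(
    config: ScreenSimConfig,
    n_replicates: int = 2,
    seed: int | None = None,
    n_ac: int = 32,
    n_nc: int = 32,
    n_compound: int = 320,
    feature_dim: int | None = None,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Duplicate-run feature tables with shared truth and independent noise."""
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    truth_rng, *rep_seqs = ss.spawn(n_replicates + 1)
    rng = np.random.default_rng(truth_rng)
    compound_ids = [f"C{i + 1:04d}" for i in range(n_compound)]
    comp_wells = [f"CW{i:03d}" for i in range(n_compound)]
    truth = _draw_truth(compound_ids, comp_wells, config, rng)
    tables = {}
    for rep, sub in enumerate(rep_seqs, start=1):
        df, _ = simulate_feature_table(
            config,
            n_ac=n_ac,
            n_nc=n_nc,
            n_compound=n_compound,
            feature_dim=feature_dim,
            seed=np.random.default_rng(sub),
            truth=truth,
        )
        tables[rep] = df
    return tables, truth


# --------------------------------------------------------------------------
# full image screen
# --------------------------------------------------------------------------


@dataclass
class ScreenSimResult:
    """Rendered synthetic screen: layouts, ground truth, and images.

    ``images`` maps ``(plate_id, well, field)`` to arrays when kept in
    memory, or to written TIFF paths when an output directory was given.
    """

    layouts: list[PlateLayout]
    truth: pd.DataFrame
    images: dict[tuple[str, str, int], np.ndarray | Path]


def _phenotype_for_entry(
    entry: WellEntry, pheno_label: str | None, config: ScreenSimConfig
) -> PhenotypeParams | None:
    if entry.role is WellRole.EMPTY:
        return None
    if entry.role is WellRole.ACTIVE_CONTROL:
        return config.ac_params
    if entry.role is WellRole.NEGATIVE_CONTROL:
        return config.nc_params
    if pheno_label == "active":
        return _interpolate_params(config.nc_params, config.ac_params, config.active_effect)
    if pheno_label == "active_dim":
        base = _interpolate_params(config.nc_params, config.ac_params, config.active_effect)
        return _dimmer_variant(base)
    return config.nc_params


def simulate_screen(
    config: ScreenSimConfig,
    n_replicates: int = 2,
    seed: int | None = None,
    layouts: list[PlateLayout] | None = None,
    outdir: str | Path | None = None,
) -> ScreenSimResult:
    """Render a full synthetic screen (images per well per replicate plate).

    All replicates share one truth assignment; every field image is drawn
    with an independent child seed.  With ``outdir`` the images are written
    as ``<plate>_<well>_f<field>.tif`` next to plate maps and the truth CSV;
    otherwise they are returned in memory (use small configs).
    """
    import tifffile

    if layouts is None:
        layouts = [
            default_screen_layout(plate_id=f"plate{r}", replicate_id=r)
            for r in range(1, n_replicates + 1)
        ]
    first = layouts[0]
    comp_addr = first.addresses_with_role(WellRole.COMPOUND)
    compound_ids = [first.wells[a].compound_id for a in comp_addr]

    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    truth_seq, img_seq = ss.spawn(2)
    truth = _draw_truth(
        compound_ids, [str(a) for a in comp_addr], config, np.random.default_rng(truth_seq)
    )
    pheno_by_compound = truth.set_index("compound_id")["phenotype"]

    out: dict[tuple[str, str, int], np.ndarray | Path] = {}
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    per_field = config.fields_per_well
    for layout in layouts:
        for addr in sorted(layout.wells):
            entry = layout.wells[addr]
            label = (
                pheno_by_compound.get(entry.compound_id)
                if entry.role is WellRole.COMPOUND
                else None
            )
            params = _phenotype_for_entry(entry, label, config)
            for f in range(per_field):
                child = img_seq.spawn(1)[0]
                if params is None:
                    field_params = dataclasses.replace(
                        config.nc_params, objects_per_well=0.0
                    )
                else:
                    field_params = dataclasses.replace(
                        params, objects_per_well=params.objects_per_well / per_field
                    )
                img = simulate_well_image(
                    field_params,
                    image_size=config.image_size,
                    seed=np.random.default_rng(child),
                )
                key = (layout.plate_id, str(addr), f)
                if outdir_path is not None:
                    path = outdir_path / f"{layout.plate_id}_{addr}_f{f}.tif"
                    tifffile.imwrite(path, img)
                    out[key] = path
                else:
                    out[key] = img

    if outdir_path is not None:
        truth.to_csv(outdir_path / "truth.csv", index=False)
        for layout in layouts:
            write_plate_map(layout, outdir_path / f"{layout.plate_id}_map.csv")
    return ScreenSimResult(layouts=layouts, truth=truth, images=out)
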