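"""Synthetic multimodal phantom cohorts with known ground truth.

Each phantom subject consists of two co-registered volumes on the same
grid: an MR-like image (soft-tissue body, ellipsoidal tumour with a
stationary Gaussian-random-field texture, a smooth multiplicative bias
field, and a small non-zero background outside the body contour) and a
CT-like image in Hounsfield units (air background, soft-tissue body,
and configurable fractions of air- and bone-valued voxels inside the
tumour). Outcomes are drawn from a logistic or exponential proportional
hazards model on a latent image property that is *measured from the
rendered image*, so parameter-recovery tests carry no rendering
approximation error.

The tabular generator :func:`generate_feature_cohort` is a fast
substrate for the modelling stages: correlated Gaussian feature blocks
with planted effects, named after real catalogue features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import RoiMask, VolumetricImage
from .outcomes import BINARY, SURVIVAL, OutcomeData

__all__ = [
    "PhantomConfig",
    "OutcomeSpec",
    "CohortBundle",
    "generate_phantom",
    "generate_cohort",
    "generate_feature_cohort",
    "write_cohort",
]

# Soft-tissue HU window used when rendering CT phantoms; matches the
# re-segmentation window applied downstream.
HU_SOFT_LOW = -150.0
HU_SOFT_HIGH = 180.0


@dataclass
class PhantomConfig:
    """Geometry and appearance knobs for one phantom subject.

    ``texture_corr_len_mm`` is the correlation length of the Gaussian
    random field inside the tumour (``inf`` gives a constant tumour);
    ``mr_bias_amplitude`` is the relative amplitude of the smooth
    multiplicative bias field, so the field lies in ``[1-a, 1+a]``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    gtv_radius_mm: float = 8.0
    texture_corr_len_mm: float = 2.0
    texture_sd: float = 12.0
    mr_bias_amplitude: float = 0.2
    ct_air_fraction: float = 0.0
    ct_bone_fraction: float = 0.0
    noise_sd: float = 2.0
    background_offset: float = 2.0
    tissue_level: float = 100.0
    gtv_level: float = 140.0
    ct_soft_hu: float = 40.0
    body_radius_fraction: float = 0.42

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        for name in ("ct_air_fraction", "ct_bone_fraction"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.ct_air_fraction + self.ct_bone_fraction >= 1:
            raise ValueError("air + bone fractions must sum to < 1")
        if self.gtv_radius_mm <= 0 or self.texture_corr_len_mm <= 0:
            raise ValueError("radii and correlation lengths must be positive")
        half_extent = min(n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)) / 2
        if self.gtv_radius_mm >= half_extent:
            raise ValueError(
                f"GTV radius {self.gtv_radius_mm} mm does not fit inside the "
                f"grid (half-extent {half_extent:.1f} mm)")


@dataclass
class OutcomeSpec:
    """Generating model linking a latent image property to the endpoint.

    ``effect_size`` is the log-odds (binary) or log-hazard (survival)
    change per standard deviation of the latent property.  ``baseline``
    is the marginal event probability (binary) or the exponential
    baseline rate per month (survival).
    """

    endpoint_kind: str = BINARY
    effect_feature: str = "mr_gtv_max"
    effect_size: float = 1.0
    baseline: float = 0.4
    censoring_rate: float = 0.02
    clinical_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.endpoint_kind not in (BINARY, SURVIVAL):
            raise ValueError(f"unknown endpoint kind {self.endpoint_kind!r}")
        if self.endpoint_kind == BINARY and not 0 < self.baseline < 1:
            raise ValueError("baseline event probability must be in (0, 1)")
        if self.endpoint_kind == SURVIVAL and self.baseline <= 0:
            raise ValueError("baseline hazard rate must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if self.effect_feature not in ("mr_gtv_max", "heterogeneity"):
            raise ValueError("effect_feature must be 'mr_gtv_max' or 'heterogeneity'")


@dataclass
class CohortBundle:
    """A generated cohort: per-subject images + masks, outcomes, truth."""

    subjects: list[dict]
    outcomes: OutcomeData
    clinical: pd.DataFrame | None
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subjects)


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return d2 <= 1.0


def _gaussian_random_field(shape, spacing, corr_len_mm, rng) -> np.ndarray:
    """Stationary GRF: white noise smoothed to the given correlation length,
    rescaled to unit variance. Infinite correlation length -> zeros."""
    white = rng.standard_normal(shape)
    if not math.isfinite(corr_len_mm):
        return np.zeros(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    if max(sigma_vox) < 1e-6:
        fld = white
    else:
        fld = ndimage.gaussian_filter(white, sigma_vox, mode="mirror")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def _bias_field(shape, spacing, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field in [1-a, 1+a]: random low-order polynomial
    in normalised coordinates, max-normalised."""
    if amplitude == 0:
        return np.ones(shape)
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")
    c = rng.standard_normal(7)
    g = (c[0] * coords[0] + c[1] * coords[1] + c[2] * coords[2]
         + c[3] * coords[0] * coords[1] + c[4] * coords[1] * coords[2]
         + c[5] * coords[0] ** 2 + c[6] * coords[2] ** 2)
    peak = np.abs(g).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * g / peak


def generate_phantom(
    config: PhantomConfig,
    seed: int,
    *,
    hotspot_amplitude: float = 0.0,
    texture_sd: float | None = None,
) -> tuple[VolumetricImage, VolumetricImage, RoiMask]:
    """Render one subject: (MR image, CT image, GTV mask).

    ``hotspot_amplitude`` adds a small bright Gaussian focus inside the
    tumour (the latent property behind the binary endpoint);
    ``texture_sd`` overrides the configured texture standard deviation
    (the latent heterogeneity property).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in config.grid_shape)
    spacing = config.voxel_spacing_mm
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]
    tsd = config.texture_sd if texture_sd is None else float(texture_sd)

    body = _ellipsoid_mask(shape, spacing, center,
                           [config.body_radius_fraction * e for e in extent])
    gtv = _ellipsoid_mask(shape, spacing, center, [config.gtv_radius_mm] * 3)
    if not gtv.any():
        raise ValueError("GTV mask is empty; increase radius or grid")
    # keep a single connected component (ellipsoids are connected by
    # construction; assert rather than repair)
    _, n_comp = ndimage.label(gtv)
    assert n_comp == 1

    texture = _gaussian_random_field(shape, spacing, config.texture_corr_len_mm, rng)

    # ---- MR ----
    mr = np.full(shape, config.background_offset)
    mr[body] = config.tissue_level
    mr[gtv] = config.gtv_level + tsd * texture[gtv]
    if hotspot_amplitude != 0.0:
        hot_sigma_mm = max(config.gtv_radius_mm / 3.0, 1.0)
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                            indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        mr[gtv] += hotspot_amplitude * np.exp(-d2 / (2 * hot_sigma_mm ** 2))[gtv]
    bias = _bias_field(shape, spacing, config.mr_bias_amplitude, rng)
    mr_noise = rng.standard_normal(shape) * config.noise_sd
    mr_img = np.clip(mr * bias + mr_noise, 0.0, None)

    # ---- CT ----
    ct = np.full(shape, -1000.0)
    soft = config.ct_soft_hu + 0.25 * tsd * texture
    ct[body] = soft[body]
    ct_noise = rng.standard_normal(shape) * config.noise_sd
    ct += ct_noise
    # soft-tissue voxels are guaranteed inside the HU window
    ct[body] = np.clip(ct[body], HU_SOFT_LOW, HU_SOFT_HIGH)
    gtv_idx = np.flatnonzero(gtv.ravel())
    n_gtv = gtv_idx.size
    n_air = int(round(config.ct_air_fraction * n_gtv))
    n_bone = int(round(config.ct_bone_fraction * n_gtv))
    special = rng.choice(gtv_idx, size=n_air + n_bone, replace=False)
    flat = ct.ravel()
    flat[special[:n_air]] = rng.uniform(-800.0, -300.0, n_air)
    flat[special[n_air:]] = rng.uniform(400.0, 1000.0, n_bone)
    ct = flat.reshape(shape)

    truth_meta = {"bias_range": (float(bias[body].min()), float(bias[body].max())),
                  "texture_sd": tsd, "hotspot_amplitude": hotspot_amplitude,
                  "n_air": n_air, "n_bone": n_bone,
                  "body_mask_voxels": int(body.sum())}
    mr_out = VolumetricImage(mr_img, spacing, modality="MR",
                             meta={"truth": truth_meta, "body_mask": body})
    ct_out = VolumetricImage(ct, spacing, modality="CT", meta={"truth": truth_meta})
    return mr_out, ct_out, RoiMask(gtv, spacing)


def _draw_outcomes(prop_std: np.ndarray, spec: OutcomeSpec, rng,
                   clinical_lin: np.ndarray | None = None):
    n = prop_std.size
    lin = spec.effect_size * prop_std
    if clinical_lin is not None:
        lin = lin + clinical_lin
    if spec.endpoint_kind == BINARY:
        eta = math.log(spec.baseline / (1 - spec.baseline)) + lin
        p = 1.0 / (1.0 + np.exp(-eta))
        labels = (rng.uniform(size=n) < p).astype(int)
        return {"labels": labels}
    hazard = spec.baseline * np.exp(lin)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        cens = np.full(n, np.inf)
    times = np.minimum(event_time, cens)
    events = (event_time <= cens).astype(int)
    times = np.maximum(times, 1e-6)
    return {"times": times, "events": events}


def generate_cohort(config: PhantomConfig, outcome: OutcomeSpec, n: int,
                    seed: int, max_attempts: int = 100) -> CohortBundle:
    """Generate ``n`` phantom subjects with outcomes tied to an image property.

    The latent property is measured from the rendered images: the in-GTV
    MR maximum for ``mr_gtv_max`` (driven by a variable hotspot) or the
    in-GTV MR standard deviation for ``heterogeneity`` (driven by a
    variable texture amplitude). Degenerate all-one-class label draws
    are retried with an incremented seed.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 subjects")
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n)

    # Anatomical variability across the cohort: tumour size, texture
    # amplitude and tissue level vary per subject so that between-subject
    # feature variance (the ICC signal) is realistic.
    subjects, props, truth_subjects = [], [], []
    import dataclasses as _dc
    half_extent = min(m * s for m, s in zip(config.grid_shape,
                                            config.voxel_spacing_mm)) / 2
    for i in range(n):
        srng = np.random.default_rng(subject_seeds[i])
        radius = float(min(config.gtv_radius_mm * srng.uniform(0.6, 1.4),
                           0.9 * half_extent))
        tissue = float(config.tissue_level * srng.uniform(0.85, 1.15))
        contrast = float(srng.uniform(1.2, 1.7))
        tsd = float(config.texture_sd * srng.uniform(0.7, 1.5))
        ct_soft = float(srng.uniform(20.0, 60.0))
        sub_cfg = _dc.replace(config, gtv_radius_mm=radius,
                              tissue_level=tissue,
                              gtv_level=tissue * contrast,
                              ct_soft_hu=ct_soft)
        hot = 0.0
        if outcome.effect_feature == "mr_gtv_max":
            hot = float(srng.uniform(0.0, 60.0))
            mr, ct, mask = generate_phantom(sub_cfg, int(subject_seeds[i]),
                                            hotspot_amplitude=hot,
                                            texture_sd=tsd)
            prop = float(mr.values[mask.values].max())
        else:
            tsd = float(srng.uniform(0.3, 2.0) * config.texture_sd)
            mr, ct, mask = generate_phantom(sub_cfg, int(subject_seeds[i]),
                                            texture_sd=tsd)
            prop = float(mr.values[mask.values].std())
        sid = f"S{i:04d}"
        subjects.append({"subject_id": sid, "mr": mr, "ct": ct,
                         "mask_mr": mask, "mask_ct": mask})
        props.append(prop)
        truth_subjects.append({"subject_id": sid, "gtv_radius_mm": radius,
                               "texture_sd": tsd, "tissue_level": tissue,
                               "hotspot_amplitude": hot})

    props = np.asarray(props)
    prop_std = (props - props.mean()) / props.std(ddof=0)

    clinical = None
    clin_lin = None
    crng = np.random.default_rng(seed + 1)
    stage = crng.integers(0, 3, size=n)
    clinical = pd.DataFrame({"stage": stage},
                            index=pd.Index([s["subject_id"] for s in subjects],
                                           name="subject_id"))
    if outcome.clinical_effect:
        clin_lin = outcome.clinical_effect * (stage - stage.mean()) / max(stage.std(), 1e-9)

    # retry degenerate draws; require enough of each class / enough
    # events for downstream stratified 3-fold CV
    min_count = min(3, n // 2)
    attempts = 0
    orng = np.random.default_rng(seed + 2)
    while True:
        drawn = _draw_outcomes(prop_std, outcome, orng, clin_lin)
        attempts += 1
        if "labels" in drawn and np.bincount(drawn["labels"],
                                             minlength=2).min() < min_count:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"degenerate label draw after {max_attempts} attempts")
            orng = np.random.default_rng(seed + 2 + attempts)
            continue
        if "events" in drawn and drawn["events"].sum() < min_count:
            if attempts >= max_attempts:
                raise RuntimeError(f"too few events after {max_attempts} draws")
            orng = np.random.default_rng(seed + 2 + attempts)
            continue
        break

    ids = [s["subject_id"] for s in subjects]
    outcomes = OutcomeData(ids, **drawn)
    truth = {"config": vars(config).copy(), "outcome_spec": vars(outcome).copy(),
             "seed": seed, "subject_seeds": subject_seeds.tolist(),
             "subjects": truth_subjects,
             "latent_property": props.tolist(),
             "latent_property_std": prop_std.tolist(),
             "outcome_draw_attempts": attempts}
    return CohortBundle(subjects, outcomes, clinical, truth)


def _block_covariance(p: int, correlation_blocks) -> np.ndarray:
    cov = np.eye(p)
    start = 0
    for bi, (size, rho) in enumerate(correlation_blocks or []):
        if start + size > p:
            raise ValueError(f"correlation block {bi} exceeds feature count")
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        try:
            np.linalg.cholesky(block)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"correlation block {bi} (size={size}, rho={rho}) is not "
                "positive definite") from None
        cov[start:start + size, start:start + size] = block
        start += size
    return cov


def generate_feature_cohort(
    n: int,
    p: int,
    planted: dict[str, float] | None = None,
    correlation_blocks: list[tuple[int, float]] | None = None,
    endpoint_kind: str = BINARY,
    seed: int = 0,
    *,
    baseline: float = 0.4,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.01,
    feature_names: list[str] | None = None,
) -> tuple[pd.DataFrame, OutcomeData]:
    """Fast tabular cohort: correlated Gaussian features + planted outcome.

    Features are multivariate normal with the requested within-block
    correlations; the outcome follows a logistic (binary) or exponential
    proportional-hazards (survival) model on the planted columns.
    Columns are named after real catalogue features so downstream stages
    see convention-compliant names.
    """
    if feature_names is None:
        from .features.catalogue import feature_names as catalogue_names
        feature_names = catalogue_names("MR")[:p]
        if len(feature_names) < p:
            feature_names = feature_names + [
                f"MR_extra_{i}" for i in range(p - len(feature_names))]
    if planted:
        missing = set(planted) - set(feature_names)
        if missing:
            raise ValueError(f"planted features not among columns: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    cov = _block_covariance(p, correlation_blocks)
    chol = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, p)) @ chol.T
    table = pd.DataFrame(X, columns=feature_names,
                         index=pd.Index([f"S{i:04d}" for i in range(n)],
                                        name="subject_id"))

    lin = np.zeros(n)
    for name, coef in (planted or {}).items():
        lin += coef * table[name].to_numpy()

    if endpoint_kind == BINARY:
        eta = math.log(baseline / (1 - baseline)) + lin
        labels = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        if len(np.unique(labels)) < 2:  # degenerate draw; flip one subject
            labels[rng.integers(n)] = 1 - labels[0]
        out = OutcomeData(list(table.index), labels=labels)
    elif endpoint_kind == SURVIVAL:
        hazard = baseline_hazard * np.exp(lin)
        t_event = rng.exponential(1.0 / hazard)
        cens = (rng.exponential(1.0 / censoring_rate, size=n)
                if censoring_rate > 0 else np.full(n, np.inf))
        times = np.maximum(np.minimum(t_event, cens), 1e-6)
        events = (t_event <= cens).astype(int)
        if events.sum() == 0:
            events[np.argmin(times)] = 1
        out = OutcomeData(list(table.index), times=times, events=events)
    else:
        raise ValueError(f"unknown endpoint kind {endpoint_kind!r}")
    return table, out


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write NIfTI images/masks, outcome and clinical CSVs, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in bundle.subjects:
        sid = s["subject_id"]
        paths = {}
        for key, obj in (("mr", s["mr"]), ("ct", s["ct"]),
                         ("mask_mr", s["mask_mr"]), ("mask_ct", s["mask_ct"])):
            path = out / f"{sid}_{key}.nii.gz"
            obj.to_nifti(path)
            paths[key] = path.name
        entries.append({"subject_id": sid, **paths})
    bundle.outcomes.to_frame().to_csv(out / "outcomes.csv")
    if bundle.clinical is not None:
        bundle.clinical.to_csv(out / "clinical.csv")
    manifest = {
        "subjects": entries,
        "outcomes": "outcomes.csv",
        "clinical": "clinical.csv" if bundle.clinical is not None else None,
        "truth": {k: v for k, v in bundle.truth.items() if k != "subjects"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out / "manifest.json"
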