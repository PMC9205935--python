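"""Image preparation before feature extraction.

The MR chain is: body-mask the image (Canny-based soft-tissue mask, the
background set to exactly zero), estimate and divide out a smooth
multiplicative bias field, scale intensities by the in-body 95th
percentile, resample to 1 mm isotropic voxels, and compute the averaged
Laplacian-of-Gaussian (LoG) response map. The CT chain is: resample,
re-segment the GTV to the soft-tissue Hounsfield window [-150, 180]
(this restricts the *extraction* ROI for intensity and texture features
only), and compute the LoG map on the full image.

The default bias corrector fits a low-order polynomial to the log
intensities inside the body mask; any callable with the same contract
(image, mask, config) -> field can be plugged in instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from .grids import RoiMask, VolumetricImage, check_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "soft_tissue_mask",
    "mask_background",
    "correct_bias_field",
    "scale_to_percentile",
    "resample_isotropic",
    "resegment_hu",
    "log_filter_bank",
    "preprocess_mr",
    "preprocess_ct",
    "PreprocessedSubject",
    "preprocess_subject",
]


@dataclass
class PreprocessConfig:
    percentile: float = 95.0
    iso_spacing_mm: float = 1.0
    hu_window: tuple[float, float] = (-150.0, 180.0)
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    canny_sigma: float = 1.5
    # Canny thresholds as fractions of the global 99.5th-percentile
    # intensity, so empty slices produce no spurious noise edges
    canny_low: float = 0.05
    canny_high: float = 0.10
    bias_poly_order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy low < high")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG kernel widths must be positive")
        if self.iso_spacing_mm <= 0:
            raise ValueError("target spacing must be positive")


def soft_tissue_mask(image: VolumetricImage, config: PreprocessConfig | None = None
                     ) -> RoiMask:
    """Body mask from slice-wise Canny edges, closed and hole-filled.

    Edges are detected per axial slice, dilated to close the contour,
    filled, and eroded back; the largest 3D connected component of the
    result is returned.
    """
    config = config or PreprocessConfig()
    if image.modality != "MR":
        raise ValueError("soft-tissue masking expects an MR image")
    vol = image.values
    scale = float(np.percentile(vol, 99.5))
    if scale <= 0:
        raise ValueError(
            "empty soft-tissue mask: image has no positive intensities; "
            "adjust canny_low/canny_high or canny_sigma")
    filled = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[2]):
        sl = vol[:, :, z]
        if sl.max() <= sl.min():
            continue
        edges = skfeature.canny(
            sl, sigma=config.canny_sigma,
            low_threshold=config.canny_low * scale,
            high_threshold=config.canny_high * scale)
        if not edges.any():
            continue
        closed = ndimage.binary_dilation(edges, iterations=2)
        closed = ndimage.binary_fill_holes(closed)
        filled[:, :, z] = ndimage.binary_erosion(closed, iterations=2)
    if not filled.any():
        raise ValueError(
            "empty soft-tissue mask: no closed Canny contour found; adjust "
            "canny_low/canny_high or canny_sigma")
    labels, n = ndimage.label(filled)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        filled = labels == counts.argmax()
    filled = ndimage.binary_fill_holes(filled)
    return RoiMask(filled, image.spacing_mm, image.origin_mm)


def mask_background(image: VolumetricImage, body_mask: RoiMask) -> VolumetricImage:
    """Multiply the image with the body mask (background exactly zero)."""
    check_aligned(image, body_mask)
    return image.with_values(image.values * body_mask.values,
                             background_masked=True)


def _poly_design(shape, order: int) -> np.ndarray:
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape],
                         indexing="ij")
    cols = [np.ones(shape).ravel()]
    for total in range(1, order + 1):
        for i in range(total + 1):
            for j in range(total + 1 - i):
                k = total - i - j
                cols.append((coords[0] ** i * coords[1] ** j
                             * coords[2] ** k).ravel())
    return np.column_stack(cols)


def correct_bias_field(image: VolumetricImage, body_mask: RoiMask,
                       config: PreprocessConfig | None = None,
                       corrector=None) -> VolumetricImage:
    """Divide out a smooth multiplicative intensity field.

    Default estimator: robust least-squares polynomial fit (order
    ``bias_poly_order``) to the log intensities inside the body mask,
    with one reweighting pass to reduce the pull of genuine anatomy.
    The in-mask mean intensity of the output equals that of the input.
    """
    config = config or PreprocessConfig()
    check_aligned(image, body_mask)
    inside = body_mask.values
    vals = image.values.copy()
    eps_shift = 0.0
    in_vals = vals[inside]
    if in_vals.min() <= 0:
        eps_shift = -in_vals.min() + 1e-3 * max(np.ptp(in_vals), 1.0)
        logger.warning("non-positive in-mask intensities; shifting by %.4g",
                       eps_shift)
        vals = vals + eps_shift

    if corrector is not None:
        fld = np.asarray(corrector(image, body_mask, config), dtype=float)
    else:
        design = _poly_design(vals.shape, config.bias_poly_order)
        d_in = design[inside.ravel()]
        y = np.log(vals[inside])
        coef, *_ = np.linalg.lstsq(d_in, y, rcond=None)
        # one robust reweighting pass: downweight voxels the smooth model
        # cannot explain (anatomy, lesions)
        resid = y - d_in @ coef
        s = max(np.median(np.abs(resid)) * 1.4826, 1e-12)
        w = 1.0 / (1.0 + (resid / (2.0 * s)) ** 2)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(d_in * sw[:, None], y * sw, rcond=None)
        fld = np.exp(design @ coef).reshape(vals.shape)

    fld = fld / fld[inside].mean()
    corrected = vals / fld - eps_shift
    mean_in = image.values[inside].mean()
    new_mean = corrected[inside].mean()
    if abs(new_mean) > 0:
        corrected = corrected * (mean_in / new_mean)
    corrected[~inside] = image.values[~inside]
    return image.with_values(corrected, bias_corrected=True,
                             bias_eps_shift=eps_shift)


def scale_to_percentile(image: VolumetricImage, body_mask: RoiMask,
                        percentile: float = 95.0) -> VolumetricImage:
    """Divide intensities by the in-mask percentile (linear interpolation).

    Intensities above the divisor are kept (values > 1), not clipped,
    so maximum-intensity information survives scaling.
    """
    check_aligned(image, body_mask)
    divisor = float(np.percentile(image.values[body_mask.values], percentile))
    if divisor == 0:
        raise ValueError("degenerate image: scaling percentile is zero")
    return image.with_values(image.values / divisor,
                             scale_percentile=percentile, scale_divisor=divisor)


def _resample_grid(values: np.ndarray, spacing, iso: float, order: int = 1
                   ) -> np.ndarray:
    new_shape = tuple(
        int(math.floor((n - 1) * s / iso + 1e-9)) + 1
        for n, s in zip(values.shape, spacing))
    coords = np.meshgrid(
        *[np.arange(m) * iso / s for m, s in zip(new_shape, spacing)],
        indexing="ij")
    return ndimage.map_coordinates(values, np.stack(coords), order=order,
                                   mode="nearest")


def resample_isotropic(image: VolumetricImage, mask: RoiMask | None = None,
                       iso_spacing_mm: float = 1.0
                       ) -> tuple[VolumetricImage, RoiMask | None]:
    """Trilinear resampling onto an isotropic grid covering the extent.

    The origin is conserved; masks are interpolated trilinearly and
    thresholded at 0.5 (ties at exactly 0.5 are foreground).
    """
    if np.allclose(image.spacing_mm, iso_spacing_mm):
        return image, mask
    new_vals = _resample_grid(image.values, image.spacing_mm, iso_spacing_mm)
    out_img = VolumetricImage(new_vals, (iso_spacing_mm,) * 3, image.origin_mm,
                              modality=image.modality,
                              meta={**image.meta, "resampled_from": image.spacing_mm})
    out_mask = None
    if mask is not None:
        check_aligned(image, mask)
        frac = _resample_grid(mask.values.astype(float), mask.spacing_mm,
                              iso_spacing_mm)
        out_mask = RoiMask(frac >= 0.5, (iso_spacing_mm,) * 3, mask.origin_mm)
    return out_img, out_mask


def resegment_hu(image: VolumetricImage, mask: RoiMask,
                 hu_window: tuple[float, float] = (-150.0, 180.0)) -> RoiMask:
    """Restrict a CT ROI to the soft-tissue HU window (bounds inclusive)."""
    if image.modality != "CT":
        raise ValueError("HU re-segmentation expects a CT image")
    check_aligned(image, mask)
    keep = mask.values & (image.values >= hu_window[0]) & (image.values <= hu_window[1])
    if not keep.any():
        raise ValueError("re-segmentation removed every ROI voxel "
                         "(no soft tissue in the ROI)")
    return mask.with_values(keep)


def _gauss_kernels_1d(sigma: float, truncate: float = 4.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(smoothing, second-derivative) kernels for one axis.

    The second-derivative kernel is corrected to sum exactly to zero
    (proportional to the Gaussian weights), so the separable LoG gives
    a strictly zero response on constant images.
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-x ** 2 / (2 * sigma ** 2))
    g /= g.sum()
    g2 = g * (x ** 2 - sigma ** 2) / sigma ** 4
    g2 -= g2.sum() * g
    return g, g2


def log_single(image: VolumetricImage, sigma_mm: float) -> np.ndarray:
    """Single-width LoG response (plain, not scale-normalised); mirror padding."""
    sigma_vox = [sigma_mm / s for s in image.spacing_mm]
    if min(sigma_vox) < 0.5:
        logger.warning("LoG sigma %.2f mm is below half a voxel", sigma_mm)
    kernels = [_gauss_kernels_1d(s) for s in sigma_vox]
    out = np.zeros_like(image.values)
    for axis in range(3):
        tmp = image.values
        for j in range(3):
            kern = kernels[j][1] if j == axis else kernels[j][0]
            tmp = ndimage.correlate1d(tmp, kern, axis=j, mode="mirror")
        out += tmp
    return out


def log_filter_bank(image: VolumetricImage,
                    sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
                    ) -> VolumetricImage:
    """Voxel-wise mean of single-width LoG responses over the filter bank."""
    responses = [log_single(image, s) for s in sigmas_mm]
    mean_map = np.mean(responses, axis=0)
    return VolumetricImage(mean_map, image.spacing_mm, image.origin_mm,
                           modality="LOG",
                           meta={**image.meta, "log_sigmas_mm": tuple(sigmas_mm),
                                 "log_base_modality": image.modality})


@dataclass
class PreprocessedSubject:
    """Everything feature extraction needs for one subject."""
    mr: VolumetricImage
    mr_log: VolumetricImage
    mr_mask: RoiMask
    ct: VolumetricImage
    ct_log: VolumetricImage
    ct_mask_morph: RoiMask       # original GTV, for morphology
    ct_mask_intensity: RoiMask   # HU re-segmented, for intensity/texture
    provenance: dict = field(default_factory=dict)


def preprocess_mr(mr: VolumetricImage, gtv: RoiMask,
                  config: PreprocessConfig | None = None,
                  body_mask: RoiMask | None = None):
    """MR chain: mask -> bias-correct -> scale -> resample -> LoG."""
    config = config or PreprocessConfig()
    prov: dict = {}
    if body_mask is None:
        body_mask = soft_tissue_mask(mr, config)
    masked = mask_background(mr, body_mask)
    corrected = correct_bias_field(masked, body_mask, config)
    scaled = scale_to_percentile(corrected, body_mask, config.percentile)
    prov["scale_divisor"] = scaled.meta["scale_divisor"]
    iso_img, iso_gtv = resample_isotropic(scaled, gtv, config.iso_spacing_mm)
    log_img = log_filter_bank(iso_img, config.log_sigmas_mm)
    prov["log_sigmas_mm"] = list(config.log_sigmas_mm)
    return iso_img, log_img, iso_gtv, body_mask, prov


def preprocess_ct(ct: VolumetricImage, gtv: RoiMask,
                  config: PreprocessConfig | None = None):
    """CT chain: resample -> HU re-segment (extraction ROI) -> LoG."""
    config = config or PreprocessConfig()
    iso_img, iso_gtv = resample_isotropic(ct, gtv, config.iso_spacing_mm)
    reseg = resegment_hu(iso_img, iso_gtv, config.hu_window)
    log_img = log_filter_bank(iso_img, config.log_sigmas_mm)
    prov = {"hu_window": list(config.hu_window),
            "resegmented_voxels": reseg.n_voxels,
            "log_sigmas_mm": list(config.log_sigmas_mm)}
    return iso_img, log_img, iso_gtv, reseg, prov


def preprocess_subject(mr: VolumetricImage, ct: VolumetricImage,
                       mask_mr: RoiMask, mask_ct: RoiMask,
                       config: PreprocessConfig | None = None,
                       mr_body_mask: RoiMask | None = None) -> PreprocessedSubject:
    config = config or PreprocessConfig()
    mr_iso, mr_log, mr_gtv, body, prov_mr = preprocess_mr(
        mr, mask_mr, config, body_mask=mr_body_mask)
    ct_iso, ct_log, ct_gtv, ct_reseg, prov_ct = preprocess_ct(ct, mask_ct, config)
    return PreprocessedSubject(
        mr=mr_iso, mr_log=mr_log, mr_mask=mr_gtv,
        ct=ct_iso, ct_log=ct_log,
        ct_mask_morph=ct_gtv, ct_mask_intensity=ct_reseg,
        provenance={"mr": prov_mr, "ct": prov_ct})
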