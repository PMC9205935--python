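"""Drivers that turn preprocessed subjects into catalogue-complete vectors."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..grids import RoiMask, VolumetricImage
from .catalogue import N_BINS_DEFAULT, feature_name, feature_names
from .discretise import discretise_fbn
from .first_order import extract_first_order
from .morphology import extract_morphology
from .texture import extract_texture


def extract_modality(base: VolumetricImage, log_img: VolumetricImage,
                     mask_morph: RoiMask, mask_intensity: RoiMask,
                     modality: str, n_bins: int = N_BINS_DEFAULT
                     ) -> dict[str, float]:
    """The full 234-feature vector for one modality of one subject.

    Morphology uses the original (non-re-segmented) mask; intensity,
    histogram and texture features use the intensity mask (for CT the
    HU re-segmented one). The LoG first-order features use the same
    intensity mask.
    """
    out: dict[str, float] = {}
    morph = extract_morphology(mask_morph.values, base.values, base.spacing_mm)
    morph.pop("_flags", None)
    for key, val in morph.items():
        out[f"{modality}_{key}"] = val

    fo = extract_first_order(base.values, mask_intensity.values, n_bins)
    for key, val in fo.items():
        fam, feat = key.split("_", 1)
        out[feature_name(modality, fam, feat, n_bins=n_bins)] = val

    disc = discretise_fbn(base.values, mask_intensity.values, n_bins)
    tex = extract_texture(disc, morph_mask=mask_morph.values)
    for fam, feats in tex.items():
        for key, val in feats.items():
            out[feature_name(modality, fam, key, n_bins=n_bins)] = val

    fo_log = extract_first_order(log_img.values, mask_intensity.values, n_bins)
    for key, val in fo_log.items():
        fam, feat = key.split("_", 1)
        out[feature_name(modality, fam, feat, log=True, n_bins=n_bins)] = val

    expected = feature_names(modality, n_bins)
    vec = {name: float(out[name]) for name in expected}
    bad = [n for n, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise AssertionError(f"non-finite features for {modality}: {bad[:5]}")
    return vec


def extract_all(subject, n_bins: int = N_BINS_DEFAULT) -> dict[str, float]:
    """MR + CT feature vector (2 x 234 values) from a preprocessed subject."""
    vec = extract_modality(subject.mr, subject.mr_log, subject.mr_mask,
                           subject.mr_mask, "MR", n_bins)
    vec.update(extract_modality(subject.ct, subject.ct_log,
                                subject.ct_mask_morph,
                                subject.ct_mask_intensity, "CT", n_bins))
    return vec


def vectors_to_table(vectors: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Stack per-subject vectors into a subjects x features table."""
    table = pd.DataFrame.from_dict(vectors, orient="index")
    table.index.name = "subject_id"
    return table
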