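"""The feature catalogue: the single source of truth for names and counts.

Per modality the catalogue comprises 234 features: 25 morphological,
57 first-order (25 intensity statistics + 32 intensity-histogram
features on the 32-bin fixed-bin-number discretisation), 95 texture
features from six matrix families (GLCM 25, GLRLM 16, GLSZM 16,
GLDZM 16, NGTDM 5, NGLDM 17), and the same 57 first-order features on
the averaged Laplacian-of-Gaussian image.

Names encode modality, image (base vs ``log``), family, feature key and
discretisation, e.g. ``CT_cm_corr_d1_3d_v_mrg_fbn_n32`` (GLCM
correlation, Chebyshev distance 1, 3D merged-volume aggregation, 32-bin
FBN) or ``MR_log_stat_min`` (minimum intensity on the LoG image).
"""

from __future__ import annotations

N_BINS_DEFAULT = 32

MORPH_KEYS = (
    "volume", "av", "area_mesh", "sv_ratio",
    "comp_1", "comp_2", "sph_dispr", "sphericity", "asphericity",
    "com", "diam",
    "pca_maj_axis", "pca_min_axis", "pca_least_axis",
    "pca_elongation", "pca_flatness",
    "v_dens_aabb", "a_dens_aabb", "v_dens_aee", "a_dens_aee",
    "v_dens_conv_hull", "a_dens_conv_hull",
    "integ_int", "moran_i", "geary_c",
)

STAT_KEYS = (
    "mean", "var", "sd", "skew", "kurt", "median", "min",
    "p5", "p10", "p25", "p75", "p90", "p95", "max",
    "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
    "energy", "rms", "sum", "tmean",
)

IH_KEYS = (
    "mean", "var", "sd", "skew", "kurt", "median", "mode", "min",
    "p5", "p10", "p25", "p75", "p90", "p95", "max",
    "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
    "entropy", "uniformity", "sum", "tmean", "n_levels",
    "max_grad", "max_grad_g", "min_grad", "min_grad_g", "grad_range",
)

GLCM_KEYS = (
    "joint_max", "joint_avg", "joint_var", "joint_entr",
    "diff_avg", "diff_var", "diff_entr",
    "sum_avg", "sum_var", "sum_entr",
    "energy", "contrast", "dissimilarity",
    "inv_diff", "inv_diff_norm", "inv_diff_mom", "inv_diff_mom_norm",
    "inv_var", "corr", "auto_corr",
    "clust_tend", "clust_shade", "clust_prom",
    "info_corr1", "info_corr2",
)

GLRLM_KEYS = (
    "sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
    "glnu", "glnu_norm", "rlnu", "rlnu_norm", "r_perc",
    "gl_var", "rl_var", "rl_entr",
)

GLSZM_KEYS = (
    "sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
    "glnu", "glnu_norm", "zsnu", "zsnu_norm", "z_perc",
    "gl_var", "zs_var", "zs_entr",
)

GLDZM_KEYS = (
    "sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
    "glnu", "glnu_norm", "zdnu", "zdnu_norm", "z_perc",
    "gl_var", "zd_var", "zd_entr",
)

NGTDM_KEYS = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_KEYS = (
    "lde", "hde", "lgce", "hgce", "ldlge", "ldhge", "hdlge", "hdhge",
    "glnu", "glnu_norm", "dcnu", "dcnu_norm", "dc_perc",
    "gl_var", "dc_var", "dc_entr", "dc_energy",
)

FAMILY_KEYS = {
    "morph": MORPH_KEYS, "stat": STAT_KEYS, "ih": IH_KEYS,
    "glcm": GLCM_KEYS, "glrlm": GLRLM_KEYS, "glszm": GLSZM_KEYS,
    "gldzm": GLDZM_KEYS, "ngtdm": NGTDM_KEYS, "ngldm": NGLDM_KEYS,
}

# texture families in catalogue order with their name templates
_TEXTURE_PREFIX = {
    "glcm": "cm_{key}_d1_3d_v_mrg",
    "glrlm": "rlm_{key}_3d_v_mrg",
    "glszm": "szm_{key}_3d",
    "gldzm": "dzm_{key}_3d",
    "ngtdm": "ngt_{key}_d1_3d",
    "ngldm": "ngl_{key}_d1_a0_0_3d",
}


def feature_name(modality: str, family: str, key: str, *, log: bool = False,
                 n_bins: int = N_BINS_DEFAULT) -> str:
    """Assemble one convention-compliant feature name."""
    stem = f"{modality}_log" if log else modality
    if family == "morph":
        return f"{stem}_morph_{key}"
    if family == "stat":
        return f"{stem}_stat_{key}"
    if family == "ih":
        return f"{stem}_ih_{key}_fbn_n{n_bins}"
    if family in _TEXTURE_PREFIX:
        return f"{stem}_{_TEXTURE_PREFIX[family].format(key=key)}_fbn_n{n_bins}"
    raise ValueError(f"unknown feature family {family!r}")


def first_order_names(modality: str, *, log: bool = False,
                      n_bins: int = N_BINS_DEFAULT) -> list[str]:
    return ([feature_name(modality, "stat", k, log=log) for k in STAT_KEYS]
            + [feature_name(modality, "ih", k, log=log, n_bins=n_bins)
               for k in IH_KEYS])


def texture_names(modality: str, n_bins: int = N_BINS_DEFAULT) -> list[str]:
    out = []
    for fam in ("glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm"):
        out += [feature_name(modality, fam, k, n_bins=n_bins)
                for k in FAMILY_KEYS[fam]]
    return out


def morphology_names(modality: str) -> list[str]:
    return [feature_name(modality, "morph", k) for k in MORPH_KEYS]


def feature_names(modality: str, n_bins: int = N_BINS_DEFAULT) -> list[str]:
    """The full per-modality catalogue, in canonical order (length 234)."""
    return (morphology_names(modality)
            + first_order_names(modality, n_bins=n_bins)
            + texture_names(modality, n_bins=n_bins)
            + first_order_names(modality, log=True, n_bins=n_bins))


def family_of(name: str) -> str:
    """Coarse feature class of a catalogue name: MFO, SOT or LoG."""
    base = name.split("_", 1)[1]
    if base.startswith("log_"):
        return "LoG"
    if base.startswith(("morph_", "stat_", "ih_")):
        return "MFO"
    return "SOT"
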