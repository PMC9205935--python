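"""Grey-level texture matrices and their features, computed in 3D.

All families use Chebyshev distance 1 (26-connectivity, 13 unique
direction pairs). GLCM and GLRLM use merged-volume aggregation: the
matrices of all directions are summed before features are computed.
GLSZM/GLDZM zones are 26-connected; GLDZM distances are city-block
distances to the morphological ROI edge (edge voxels have distance 1).
NGTDM/NGLDM use the Chebyshev-1 neighbourhood; the NGLDM dependence
count is 1 + the number of neighbours with an identical grey level
(tolerance 0), so counts start at 1.

Matrix entries are integer counts; the tests check them against
exhaustive pair/run/zone enumeration on tiny instances. Probabilities
are counts divided by the total; entropies are in bits. Degenerate
cases (no pairs, a single occupied level) return the documented 0
fallbacks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .catalogue import (GLDZM_KEYS, GLRLM_KEYS, GLSZM_KEYS, NGLDM_KEYS,
                        NGTDM_KEYS)
from .discretise import DiscretisedRoi

DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shift_pair(shape, d):
    """Slices (src, dst) such that arr[src] and arr[dst] pair x with x+d."""
    src, dst = [], []
    for n, di in zip(shape, d):
        if di >= 0:
            src.append(slice(0, n - di))
            dst.append(slice(di, n))
        else:
            src.append(slice(-di, n))
            dst.append(slice(0, n + di))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM

def glcm_matrix(disc: DiscretisedRoi) -> np.ndarray:
    """Symmetric merged-volume co-occurrence counts, shape (K, K)."""
    lv, k = disc.levels, disc.n_bins
    mat = np.zeros((k, k), dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _shift_pair(lv.shape, d)
        a, b = lv[src].ravel(), lv[dst].ravel()
        ok = (a > 0) & (b > 0)
        pairs = np.bincount((a[ok] - 1) * k + (b[ok] - 1), minlength=k * k)
        mat += pairs.reshape(k, k)
    return mat + mat.T


def glcm_features(mat: np.ndarray) -> dict[str, float]:
    k = mat.shape[0]
    ns = mat.sum()
    if ns == 0:
        from .catalogue import GLCM_KEYS
        return {key: 0.0 for key in GLCM_KEYS}
    p = mat / ns
    i = np.arange(1, k + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)

    out: dict[str, float] = {}
    out["joint_max"] = float(p.max())
    mu = float((ii * p).sum())
    out["joint_avg"] = mu
    out["joint_var"] = float(((ii - mu) ** 2 * p).sum())
    pos = p[p > 0]
    hxy = float(-(pos * np.log2(pos)).sum())
    out["joint_entr"] = hxy

    # difference and sum distributions
    diff = np.abs(ii - jj)
    p_d = np.bincount(diff.ravel(), weights=p.ravel(), minlength=k)
    kd = np.arange(k)
    mu_d = float((kd * p_d).sum())
    out["diff_avg"] = mu_d
    out["diff_var"] = float(((kd - mu_d) ** 2 * p_d).sum())
    pdp = p_d[p_d > 0]
    out["diff_entr"] = float(-(pdp * np.log2(pdp)).sum())

    ssum = ii + jj
    p_s = np.bincount(ssum.ravel(), weights=p.ravel(), minlength=2 * k + 1)[2:]
    ks = np.arange(2, 2 * k + 1)
    mu_s = float((ks * p_s).sum())
    out["sum_avg"] = mu_s
    out["sum_var"] = float(((ks - mu_s) ** 2 * p_s).sum())
    psp = p_s[p_s > 0]
    out["sum_entr"] = float(-(psp * np.log2(psp)).sum())

    out["energy"] = float((p ** 2).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["dissimilarity"] = float((diff * p).sum())
    out["inv_diff"] = float((p / (1 + diff)).sum())
    out["inv_diff_norm"] = float((p / (1 + diff / k)).sum())
    out["inv_diff_mom"] = float((p / (1 + diff ** 2)).sum())
    out["inv_diff_mom_norm"] = float((p / (1 + diff ** 2 / k ** 2)).sum())
    off = diff > 0
    out["inv_var"] = float((p[off] / diff[off] ** 2).sum())

    var_x = float(((i - mu) ** 2 * px).sum())
    if var_x > 0:
        out["corr"] = float(((ii - mu) * (jj - mu) * p).sum() / var_x)
    else:
        out["corr"] = 0.0
    out["auto_corr"] = float((ii * jj * p).sum())
    dev = ii + jj - 2 * mu
    out["clust_tend"] = float((dev ** 2 * p).sum())
    out["clust_shade"] = float((dev ** 3 * p).sum())
    out["clust_prom"] = float((dev ** 4 * p).sum())

    pxy = np.outer(px, px)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    out["info_corr1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["info_corr2"] = float(np.sqrt(max(arg, 0.0)))
    return out


# ---------------------------------------------------------------- GLRLM

def glrlm_matrix(disc: DiscretisedRoi) -> np.ndarray:
    """Merged-volume run-length counts, shape (K, max_run)."""
    lv, k = disc.levels, disc.n_bins
    shape = lv.shape
    max_len = int(np.ceil(np.sqrt(sum(s ** 2 for s in shape)))) + 1
    mat = np.zeros((k, max_len + 1), dtype=np.int64)
    for d in DIRECTIONS_13:
        # run starts: in-ROI voxels whose predecessor along -d differs
        prev = np.zeros(shape, dtype=lv.dtype)
        src, dst = _shift_pair(shape, d)
        prev[dst] = lv[src]
        starts = (lv > 0) & (prev != lv)
        pos = np.argwhere(starts)
        lvl = lv[starts]
        if len(pos) == 0:
            continue
        length = np.ones(len(pos), dtype=np.int64)
        active = np.ones(len(pos), dtype=bool)
        cur = pos.copy()
        darr = np.asarray(d)
        while active.any():
            idx_active = np.flatnonzero(active)
            cur_a = cur[idx_active] + darr
            inside = np.all((cur_a >= 0) & (cur_a < shape), axis=1)
            same = np.zeros(len(cur_a), dtype=bool)
            if inside.any():
                ci = cur_a[inside]
                same[inside] = (lv[ci[:, 0], ci[:, 1], ci[:, 2]]
                                == lvl[idx_active][inside])
            length[idx_active[same]] += 1
            cur[idx_active[same]] += darr
            active[idx_active[~same]] = False
        np.add.at(mat, (lvl - 1, length), 1)
    return mat[:, 1:]


def _run_family(mat: np.ndarray, n_vox: int, keys, perc_denominator: float
                ) -> dict[str, float]:
    """Shared feature set of the run/zone/distance matrix families.

    ``keys`` supplies the family's naming of the generic 16 features in
    canonical order (small emphasis, large emphasis, ... entropy).
    """
    ns = mat.sum()
    if ns == 0:
        return {key: 0.0 for key in keys}
    k, jmax = mat.shape
    i = np.arange(1, k + 1, dtype=float)
    j = np.arange(1, jmax + 1, dtype=float)
    r_i = mat.sum(axis=1).astype(float)
    c_j = mat.sum(axis=0).astype(float)
    p = mat / ns
    ii, jj = np.meshgrid(i, j, indexing="ij")

    vals = [
        float((c_j / j ** 2).sum() / ns),              # small emphasis
        float((c_j * j ** 2).sum() / ns),              # large emphasis
        float((r_i / i ** 2).sum() / ns),              # low grey level
        float((r_i * i ** 2).sum() / ns),              # high grey level
        float((mat / (ii ** 2 * jj ** 2)).sum() / ns),
        float((mat * ii ** 2 / jj ** 2).sum() / ns),
        float((mat * jj ** 2 / ii ** 2).sum() / ns),
        float((mat * ii ** 2 * jj ** 2).sum() / ns),
        float((r_i ** 2).sum() / ns),                  # glnu
        float((r_i ** 2).sum() / ns ** 2),             # glnu_norm
        float((c_j ** 2).sum() / ns),                  # size/length non-unif
        float((c_j ** 2).sum() / ns ** 2),
        float(ns / perc_denominator),                  # percentage
    ]
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    vals.append(float(((ii - mu_i) ** 2 * p).sum()))   # gl_var
    vals.append(float(((jj - mu_j) ** 2 * p).sum()))   # size var
    pos = p[p > 0]
    vals.append(float(-(pos * np.log2(pos)).sum()))    # entropy
    return dict(zip(keys, vals))


def glrlm_features(mat: np.ndarray, n_vox: int) -> dict[str, float]:
    return _run_family(mat, n_vox, GLRLM_KEYS,
                       perc_denominator=n_vox * len(DIRECTIONS_13))


# ---------------------------------------------------------------- GLSZM

def glszm_matrix(disc: DiscretisedRoi) -> np.ndarray:
    """Zone-size counts, shape (K, max_zone_size)."""
    lv, k = disc.levels, disc.n_bins
    n_roi = int(disc.roi.sum())
    mat = np.zeros((k, n_roi + 1), dtype=np.int64)
    for g in np.unique(lv[lv > 0]):
        lab, nz = ndimage.label(lv == g, structure=_STRUCT26)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(mat, (g - 1, sizes), 1)
    return mat[:, 1:]


def glszm_features(mat: np.ndarray, n_vox: int) -> dict[str, float]:
    return _run_family(mat, n_vox, GLSZM_KEYS, perc_denominator=n_vox)


# ---------------------------------------------------------------- GLDZM

def roi_distance_map(morph_mask: np.ndarray) -> np.ndarray:
    """City-block distance to outside the ROI; edge voxels get 1."""
    padded = np.pad(morph_mask.astype(bool), 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1]


def gldzm_matrix(disc: DiscretisedRoi, morph_mask: np.ndarray | None = None
                 ) -> np.ndarray:
    """Zone-distance counts, shape (K, max_distance)."""
    lv, k = disc.levels, disc.n_bins
    morph = disc.roi if morph_mask is None else np.asarray(morph_mask, bool)
    dmap = roi_distance_map(morph)
    dmax = int(dmap.max()) if dmap.max() > 0 else 1
    mat = np.zeros((k, dmax + 1), dtype=np.int64)
    for g in np.unique(lv[lv > 0]):
        lab, nz = ndimage.label(lv == g, structure=_STRUCT26)
        if nz == 0:
            continue
        inz = lab > 0
        dmin = np.full(nz + 1, np.iinfo(np.int64).max)
        np.minimum.at(dmin, lab[inz], dmap[inz])
        # intensity-mask zones outside the morph mask edge still count 1
        dmin = np.maximum(dmin[1:], 1).astype(int)
        np.add.at(mat, (g - 1, dmin), 1)
    return mat[:, 1:]


def gldzm_features(mat: np.ndarray, n_vox: int) -> dict[str, float]:
    return _run_family(mat, n_vox, GLDZM_KEYS, perc_denominator=n_vox)


# ---------------------------------------------------------------- NGTDM

def ngtdm_table(disc: DiscretisedRoi) -> tuple[np.ndarray, np.ndarray]:
    """(n_k, s_k) for levels k=1..K."""
    lv, roi, k = disc.levels, disc.roi, disc.n_bins
    kern = np.ones((3, 3, 3))
    nb_sum = ndimage.correlate(lv.astype(float) * roi, kern, mode="constant")
    nb_cnt = ndimage.correlate(roi.astype(float), kern, mode="constant")
    nb_sum = nb_sum - lv * roi
    nb_cnt = nb_cnt - roi
    valid = roi & (nb_cnt > 0)
    avg = np.zeros(lv.shape)
    avg[valid] = nb_sum[valid] / nb_cnt[valid]
    dev = np.abs(lv - avg)
    n_k = np.bincount(lv[valid], minlength=k + 1)[1:].astype(float)
    s_k = np.bincount(lv[valid], weights=dev[valid], minlength=k + 1)[1:]
    return n_k, s_k


def ngtdm_features(n_k: np.ndarray, s_k: np.ndarray) -> dict[str, float]:
    n_tot = n_k.sum()
    if n_tot == 0:
        return {key: 0.0 for key in NGTDM_KEYS}
    p = n_k / n_tot
    i = np.arange(1, len(n_k) + 1, dtype=float)
    occ = p > 0
    n_g = int(occ.sum())
    out: dict[str, float] = {}
    denom = float((p * s_k).sum())
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if n_g > 1:
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        gi, gj = np.meshgrid(i[occ], i[occ], indexing="ij")
        out["contrast"] = float(
            (pi * pj * (gi - gj) ** 2).sum() / (n_g * (n_g - 1))
            * s_k.sum() / n_tot)
        busy_den = float((np.abs(gi * pi - gj * pj)[gi != gj]).sum())
        out["busyness"] = denom / busy_den if busy_den > 0 else 0.0
        si = s_k[occ]
        si_i, si_j = np.meshgrid(si, si, indexing="ij")
        out["complexity"] = float(
            (np.abs(gi - gj) * (pi * si_i + pj * si_j) / (pi + pj)).sum()
            / n_tot)
        s_sum = float(s_k.sum())
        out["strength"] = (float(((pi + pj) * (gi - gj) ** 2).sum()) / s_sum
                           if s_sum > 0 else 0.0)
    else:
        out.update(contrast=0.0, busyness=0.0, complexity=0.0, strength=0.0)
    return {key: out[key] for key in NGTDM_KEYS}


# ---------------------------------------------------------------- NGLDM

def ngldm_matrix(disc: DiscretisedRoi) -> np.ndarray:
    """Dependence-count matrix, shape (K, 27); count = 1 + equal neighbours."""
    lv, roi, k = disc.levels, disc.roi, disc.n_bins
    eq = np.zeros(lv.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _shift_pair(lv.shape, d)
        a, b = lv[src], lv[dst]
        match = (a > 0) & (b > 0) & (a == b)
        eq[src] += match
        eq[dst] += match
    dep = (eq + 1)[roi]
    lvl = lv[roi]
    mat = np.zeros((k, 28), dtype=np.int64)
    np.add.at(mat, (lvl - 1, dep), 1)
    return mat[:, 1:]


def ngldm_features(mat: np.ndarray, n_vox: int) -> dict[str, float]:
    base = _run_family(mat, n_vox, NGLDM_KEYS[:16], perc_denominator=n_vox)
    ns = mat.sum()
    p = mat / ns if ns > 0 else mat.astype(float)
    base["dc_energy"] = float((p ** 2).sum())
    return {key: base[key] for key in NGLDM_KEYS}


# ---------------------------------------------------------------- driver

def extract_texture(disc: DiscretisedRoi, morph_mask: np.ndarray | None = None
                    ) -> dict[str, dict[str, float]]:
    """All 95 texture features, nested by family."""
    n_vox = int(disc.roi.sum())
    if n_vox < 2:
        return {
            "glcm": glcm_features(np.zeros((disc.n_bins, disc.n_bins), dtype=int)),
            "glrlm": {key: 0.0 for key in GLRLM_KEYS},
            "glszm": {key: 0.0 for key in GLSZM_KEYS},
            "gldzm": {key: 0.0 for key in GLDZM_KEYS},
            "ngtdm": {key: 0.0 for key in NGTDM_KEYS},
            "ngldm": {key: 0.0 for key in NGLDM_KEYS},
        }
    return {
        "glcm": glcm_features(glcm_matrix(disc)),
        "glrlm": glrlm_features(glrlm_matrix(disc), n_vox),
        "glszm": glszm_features(glszm_matrix(disc), n_vox),
        "gldzm": gldzm_features(gldzm_matrix(disc, morph_mask), n_vox),
        "ngtdm": ngtdm_features(*ngtdm_table(disc)),
        "ngldm": ngldm_features(ngldm_matrix(disc), n_vox),
    }
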