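"""First-order features: intensity statistics and intensity-histogram families.

Statistics are computed on the raw ROI intensities; histogram features
on the FBN-discretised levels (probabilities over the occupied part of
the 1..K grid, gradients over the full K-bin count vector). All moments
use population (ddof=0) conventions; quantiles use linear interpolation;
entropy is in bits. Zero-variance / zero-denominator cases fall back to
0 so downstream tables stay finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .catalogue import IH_KEYS, STAT_KEYS
from .discretise import DiscretisedRoi, discretise_fbn


def _moments(x: np.ndarray) -> dict:
    mu = float(x.mean())
    var = float(x.var(ddof=0))
    sd = var ** 0.5
    if sd > 0:
        skew = float(((x - mu) ** 3).mean() / sd ** 3)
        kurt = float(((x - mu) ** 4).mean() / sd ** 4) - 3.0
    else:
        skew = kurt = 0.0
    return {"mean": mu, "var": var, "sd": sd, "skew": skew, "kurt": kurt}


def _common_stats(x: np.ndarray) -> dict:
    out = _moments(x)
    q = np.percentile(x, [5, 10, 25, 50, 75, 90, 95])
    p5, p10, p25, med, p75, p90, p95 = (float(v) for v in q)
    out.update(median=med, min=float(x.min()), p5=p5, p10=p10, p25=p25,
               p75=p75, p90=p90, p95=p95, max=float(x.max()),
               iqr=p75 - p25, range=float(x.max() - x.min()))
    out["mad"] = float(np.abs(x - out["mean"]).mean())
    core = x[(x >= p10) & (x <= p90)]
    out["rmad"] = float(np.abs(core - core.mean()).mean()) if core.size else 0.0
    out["medad"] = float(np.abs(x - med).mean())
    out["cov"] = out["sd"] / out["mean"] if out["mean"] != 0 else 0.0
    out["qcod"] = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
    out["tmean"] = float(sstats.trim_mean(x, 0.1))
    return out


def stat_features(values: np.ndarray) -> dict[str, float]:
    """The 25 intensity-statistics features on raw ROI intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    out = _common_stats(x)
    out["energy"] = float((x ** 2).sum())
    out["rms"] = float(np.sqrt((x ** 2).mean()))
    out["sum"] = float(x.sum())
    return {k: out[k] for k in STAT_KEYS}


def ih_features(disc: DiscretisedRoi) -> dict[str, float]:
    """The 32 intensity-histogram features on FBN levels."""
    lv = disc.roi_levels.astype(float)
    k = disc.n_bins
    counts = np.bincount(disc.roi_levels, minlength=k + 1)[1:]  # bins 1..K
    n = lv.size
    p = counts / n

    out = _common_stats(lv)
    occupied = np.flatnonzero(counts) + 1
    out["mode"] = float(occupied[np.argmax(counts[occupied - 1])])
    pos = p[p > 0]
    out["entropy"] = float(-(pos * np.log2(pos)).sum())
    out["uniformity"] = float((p ** 2).sum())
    out["sum"] = float(lv.sum())
    out["n_levels"] = float(occupied.size)

    # histogram gradient over the full K-bin count vector
    grad = np.empty(k)
    if k == 1:
        grad[0] = 0.0
    else:
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        if k > 2:
            grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    i_max, i_min = int(np.argmax(grad)), int(np.argmin(grad))
    out["max_grad"] = float(grad[i_max])
    out["max_grad_g"] = float(i_max + 1)
    out["min_grad"] = float(grad[i_min])
    out["min_grad_g"] = float(i_min + 1)
    out["grad_range"] = float(grad[i_max] - grad[i_min])
    return {key: out[key] for key in IH_KEYS}


def extract_first_order(values: np.ndarray, roi: np.ndarray, n_bins: int = 32
                        ) -> dict[str, float]:
    """All 57 first-order features keyed ``stat_<k>`` / ``ih_<k>``."""
    roi = np.asarray(roi, dtype=bool)
    x = np.asarray(values, dtype=float)[roi]
    disc = discretise_fbn(values, roi, n_bins)
    out = {f"stat_{k}": v for k, v in stat_features(x).items()}
    out.update({f"ih_{k}": v for k, v in ih_features(disc).items()})
    return out
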