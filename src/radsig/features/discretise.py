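"""Fixed-bin-number (FBN) grey-level discretisation.

The ROI intensities are mapped to integer levels 1..K between the ROI
minimum and maximum: ``level = min(floor(K * (x - min) / (max - min)) + 1, K)``.
A constant ROI maps to level 1 everywhere. The mapping is invariant
under positive affine transforms of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretisedRoi:
    """Integer grey levels 1..K inside the ROI (0 outside)."""

    levels: np.ndarray       # 3D int array, 0 outside the ROI
    roi: np.ndarray          # boolean mask
    n_bins: int

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.roi]


def discretise_fbn(values: np.ndarray, roi: np.ndarray, n_bins: int = 32
                   ) -> DiscretisedRoi:
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("cannot discretise an empty ROI")
    x = np.asarray(values, dtype=float)
    lo, hi = x[roi].min(), x[roi].max()
    levels = np.zeros(x.shape, dtype=np.int32)
    if hi == lo:
        levels[roi] = 1
    else:
        lv = np.floor(n_bins * (x[roi] - lo) / (hi - lo)).astype(np.int32) + 1
        levels[roi] = np.minimum(lv, n_bins)
    return DiscretisedRoi(levels=levels, roi=roi, n_bins=n_bins)
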