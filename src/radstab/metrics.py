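"""Contour agreement metrics: Dice overlap and symmetric mean absolute
surface distance (SMASD), plus cohort-level scoring.

Surface voxels are foreground voxels with at least one background 6-neighbor
(voxels beyond the grid count as background).  SMASD is the pooled mean of
nearest-surface Euclidean distances taken symmetrically over both surface
sets, measured between voxel centers in voxel units by default; set
``physical=True`` to weight axes by the voxel spacing (mm).  A
``mean_of_means`` symmetrization (average of the two directed means) is
available as an option; the two agree when both surfaces have equal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .core import BinaryMask, EmptyMaskError, LesionCase, require_compatible

__all__ = ["ContourScore", "dice", "smasd", "surface_voxels", "score_cohort", "scores_to_frame"]

_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass
class ContourScore:
    """Agreement of one rater contour with its ground truth."""

    lesion_id: str
    rater_id: str
    dice: float
    smasd: float  # voxel units
    volume_error_cm3: float  # signed, rater minus ground truth
    gt_volume_cm3: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice out of range: {self.dice}")
        if self.smasd < 0:
            raise ValueError(f"smasd negative: {self.smasd}")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 0 = disjoint, 1 = identical."""
    require_compatible(b, a)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise EmptyMaskError("dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def surface_voxels(m: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background 6-neighbor (grid edge = background)."""
    eroded = ndi.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return m & ~eroded


def smasd(
    a: BinaryMask,
    b: BinaryMask,
    physical: bool = False,
    mean_of_means: bool = False,
) -> float:
    """Symmetric mean absolute surface distance between two masks.

    Computed as [Σ_{x∈S_A} d(x, S_B) + Σ_{y∈S_B} d(y, S_A)] / (|S_A| + |S_B|)
    with ``d`` the Euclidean distance to the nearest surface voxel of the
    other mask.  Returns voxel units unless ``physical`` (then mm).
    """
    require_compatible(b, a)
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise EmptyMaskError("smasd undefined for an empty mask")
    sa = np.argwhere(surface_voxels(a.data)).astype(np.float64)
    sb = np.argwhere(surface_voxels(b.data)).astype(np.float64)
    if physical:
        sa *= np.asarray(a.spacing)
        sb *= np.asarray(a.spacing)
    d_ab = cKDTree(sb).query(sa, k=1)[0]
    d_ba = cKDTree(sa).query(sb, k=1)[0]
    if mean_of_means:
        return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def score_cohort(cases: list[LesionCase]) -> list[ContourScore]:
    """One :class:`ContourScore` per (lesion, rater) pair."""
    scores = []
    for case in cases:
        gt = case.ground_truth
        vox = gt.voxel_volume_cm3
        for rid, mask in case.rater_masks.items():
            scores.append(
                ContourScore(
                    lesion_id=case.lesion_id,
                    rater_id=rid,
                    dice=dice(gt, mask),
                    smasd=smasd(gt, mask),
                    volume_error_cm3=(mask.n_voxels - gt.n_voxels) * vox,
                    gt_volume_cm3=gt.volume_cm3,
                )
            )
    return scores


def scores_to_frame(scores: list[ContourScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lesion_id": s.lesion_id,
                "rater_id": s.rater_id,
                "dice": s.dice,
                "smasd": s.smasd,
                "volume_error_cm3": s.volume_error_cm3,
                "gt_volume_cm3": s.gt_volume_cm3,
            }
            for s in scores
        ]
    )
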