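"""Peak extraction and detection-quality evaluation.

Peaks are voxels of the z-score map above a threshold (default z > 5),
selected greedily in descending z with non-maximum suppression over a ball of
half the template diameter. Detected peaks are compared against an annotated
ground truth with a distance tolerance in nanometres; true/false positives and
negatives give ROC points and the F1 score.

Note on rate definitions: the ROC sensitivity axis is the standard
TPR = TP / (TP + FN). Precision TP / (TP + FP) is reported alongside, since
both are common summaries of picking performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UnitError
from .geometry import AngleList, Orientation, angular_distance_full
from .io import ParticleList, angstrom_to_nm
from .matching import ScoreMaps

__all__ = [
    "Peak",
    "ConfusionCounts",
    "extract_peaks",
    "peaks_to_particle_list",
    "match_to_ground_truth",
    "roc_points",
    "f1_score",
    "precision",
    "recall",
]


@dataclass(frozen=True)
class Peak:
    """A local maximum of the z-score map."""

    position: tuple
    orientation: Orientation
    cc: float
    zscore: float


@dataclass
class ConfusionCounts:
    """TP/FP/FN (+ TN when a negative set is defined)."""

    TP: int
    FP: int
    FN: int
    TN: int | None = None

    def __post_init__(self):
        for name in ("TP", "FP", "FN"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.TN is not None and self.TN < 0:
            raise DomainError("TN must be >= 0")


def extract_peaks(
    maps: ScoreMaps,
    z_threshold: float = 5.0,
    min_separation: float = 1.0,
    angles: AngleList | None = None,
) -> list:
    """Greedy peak extraction from a z-score map.

    Candidates are valid (non-border) voxels with z above the threshold,
    visited in descending z; each accepted peak suppresses all candidates
    within ``min_separation`` voxels (the template-diameter/2 rule). If an
    angle list is given, each peak carries its argmax orientation.
    """
    if min_separation < 1:
        raise DomainError("min_separation must be >= 1 voxel")
    z = maps.zscore.data
    cand = np.argwhere((z > z_threshold) & maps.valid)
    if len(cand) == 0:
        return []
    zvals = z[tuple(cand.T)]
    order = np.argsort(-zvals, kind="stable")
    cand = cand[order]
    zvals = zvals[order]

    accepted: list[np.ndarray] = []
    accepted_idx: list[int] = []
    for i in range(len(cand)):
        p = cand[i]
        ok = True
        for q in accepted:
            if np.sum((p - q) ** 2) < min_separation**2:
                ok = False
                break
        if ok:
            accepted.append(p)
            accepted_idx.append(i)

    peaks = []
    for p, i in zip(accepted, accepted_idx):
        pos = tuple(int(v) for v in p)
        ai = int(maps.angle_index[pos])
        ori = angles[ai] if angles is not None else Orientation.identity()
        peaks.append(
            Peak(
                position=pos,
                orientation=ori,
                cc=float(maps.cc_max.data[pos]),
                zscore=float(zvals[i]),
            )
        )
    return peaks


def peaks_to_particle_list(peaks) -> ParticleList:
    rows = [
        {
            "x": p.position[0], "y": p.position[1], "z": p.position[2],
            "phi": p.orientation.phi, "theta": p.orientation.theta,
            "psi": p.orientation.psi, "score": p.cc, "zscore": p.zscore,
        }
        for p in peaks
    ]
    return ParticleList(pd.DataFrame(rows))


def match_to_ground_truth(
    peaks,
    gt: ParticleList,
    tolerance_nm: float,
    voxel_size: float,
):
    """One-to-one greedy matching of peaks to ground-truth particles.

    Peak/GT positions are in voxels; ``voxel_size`` (Angstrom) converts the
    distances to nanometres for the tolerance test. Pairs are matched in order
    of increasing distance (ties toward lower indices); matched GT are TP,
    unmatched GT are FN, unmatched peaks are FP.

    Returns ``(counts, matched_distances_nm, matched_angular_errors_deg)``.
    """
    if not tolerance_nm > 0:
        raise DomainError("tolerance must be > 0")
    if not voxel_size > 0:
        raise UnitError(
            "voxel_size (Angstrom) is required to compare voxel positions "
            "against a tolerance in nm"
        )
    n_gt = len(gt)
    n_pk = len(peaks)
    if n_pk == 0:
        return ConfusionCounts(0, 0, n_gt), np.array([]), np.array([])
    if n_gt == 0:
        return ConfusionCounts(0, n_pk, 0), np.array([]), np.array([])

    pk_pos = np.array([p.position for p in peaks], dtype=float)
    gt_pos = gt.positions
    d_nm = np.asarray(
        angstrom_to_nm(
            np.linalg.norm(pk_pos[:, None, :] - gt_pos[None, :, :], axis=-1)
            * voxel_size
        )
    )
    pairs = np.argwhere(d_nm <= tolerance_nm)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], d_nm[tuple(pairs.T)]))
    used_pk: set[int] = set()
    used_gt: set[int] = set()
    dists, angerrs = [], []
    gt_eul = gt.eulers
    for i, j in pairs[order]:
        if i in used_pk or j in used_gt:
            continue
        used_pk.add(int(i))
        used_gt.add(int(j))
        dists.append(d_nm[i, j])
        angerrs.append(
            angular_distance_full(
                peaks[i].orientation, Orientation(*gt_eul[j])
            )
        )
    tp = len(used_gt)
    counts = ConfusionCounts(TP=tp, FP=n_pk - tp, FN=n_gt - tp)
    return counts, np.array(dists), np.array(angerrs)


def roc_points(
    peaks,
    gt: ParticleList,
    tolerance_nm: float,
    voxel_size: float,
    thresholds=None,
):
    """ROC points (FPR, TPR) over z-score thresholds.

    The candidate set is the given peak list (extract it at a low threshold);
    candidates not within tolerance of any ground-truth particle form the
    negative set, so TN at a threshold counts the negatives rejected by it.
    If ``thresholds`` is omitted, all observed peak z-values are used.

    Returns a DataFrame with threshold, TP, FP, FN, TN, TPR, FPR, precision,
    F1 — sorted by ascending threshold.
    """
    if len(peaks) == 0:
        raise DomainError("no candidate peaks: ROC unavailable")
    counts_all, _, _ = match_to_ground_truth(
        peaks, gt, tolerance_nm, voxel_size
    )
    n_negatives = counts_all.FP  # candidates never matching GT
    if n_negatives == 0 and counts_all.TP == 0:
        raise DomainError("no negative candidates definable: ROC unavailable")
    if thresholds is None:
        thresholds = sorted({p.zscore for p in peaks})
    rows = []
    for t in thresholds:
        sel = [p for p in peaks if p.zscore >= t]
        c, _, _ = match_to_ground_truth(sel, gt, tolerance_nm, voxel_size)
        tn = n_negatives - c.FP
        c = ConfusionCounts(c.TP, c.FP, c.FN, TN=max(tn, 0))
        rows.append(
            {
                "threshold": t,
                "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN,
                "TPR": recall(c),
                "FPR": c.FP / (c.FP + c.TN) if (c.FP + c.TN) else 0.0,
                "precision": precision(c),
                "F1": f1_score(c) if (2 * c.TP + c.FP + c.FN) else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("threshold").reset_index(drop=True)


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN)."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        raise DomainError("F1 undefined for all-zero counts")
    return 2 * c.TP / denom


def precision(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0


def recall(c: ConfusionCounts) -> float:
    """Sensitivity / true positive rate TP / (TP + FN)."""
    return c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
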