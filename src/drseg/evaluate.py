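"""Segmentation metrics, exclusion policies, cohort summaries, volumetry.

Conventions: Dice is ``2|G∩P| / (|G|+|P|)``; the average surface distance is
the symmetric mean of nearest-neighbor distances between boundary-voxel
centers in world mm.  A label present in one map but missing from the other
scores Dice 0 and ASD NaN; a label absent from both is dropped from
summaries.  The default exclusion policy removes choroid plexus (both
hemispheres), WM-hypointensities, the lateral and inferior lateral
ventricles (both hemispheres), and CSF — leaving 27 of the 35 structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

from .volio import LabeledVolume

__all__ = [
    "SurfacePoints",
    "ExclusionPolicy",
    "EvalReport",
    "VolumetryRecord",
    "DEFAULT_EXCLUDED_IDS",
    "default_exclusion_policy",
    "dice_coefficient",
    "average_surface_distance",
    "evaluate_labelmaps",
    "label_volumes",
    "group_volume_test",
    "summarize_cohort",
    "bootstrap_median_ci",
]

# id -> rationale tag for the default 27-of-35 summary set
DEFAULT_EXCLUDED_IDS: dict[int, str] = {
    31: "choroid-plexus",
    63: "choroid-plexus",
    77: "wm-hypointensities",
    4: "lateral-ventricle",
    43: "lateral-ventricle",
    5: "inferior-lateral-ventricle",
    44: "inferior-lateral-ventricle",
    24: "csf",
}


@dataclass
class ExclusionPolicy:
    excluded: dict[int, str] = field(default_factory=dict)

    @property
    def ids(self) -> frozenset:
        return frozenset(self.excluded)


def default_exclusion_policy() -> ExclusionPolicy:
    return ExclusionPolicy(dict(DEFAULT_EXCLUDED_IDS))


@dataclass
class SurfacePoints:
    """World-coordinate centers of boundary voxels of one segment."""

    points_mm: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points_mm)


def _as_bool(mask) -> np.ndarray:
    data = getattr(mask, "data", mask)
    return np.asarray(data).astype(bool)


def dice_coefficient(G, P) -> float:
    """``2|G∩P| / (|G|+|P|)``; one-sided emptiness gives 0.

    Both-empty is the caller's 'missing' case and raises here."""
    g, p = _as_bool(G), _as_bool(P)
    if g.shape != p.shape:
        raise ValueError(f"grid mismatch: {g.shape} vs {p.shape}")
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        raise ValueError("both segments empty: Dice undefined (missing label)")
    return 2.0 * int((g & p).sum()) / denom


def surface_points(mask, affine: np.ndarray | None = None) -> SurfacePoints:
    """Centers of foreground voxels with >= 1 face-adjacent background voxel."""
    g = _as_bool(mask)
    if affine is None:
        affine = getattr(mask, "affine", np.eye(4))
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(g, structure=structure, border_value=0)
    boundary = g & ~interior
    idx = np.argwhere(boundary).astype(float)
    pts = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return SurfacePoints(pts)


def average_surface_distance(G, P, spacing=None, affine: np.ndarray | None = None) -> float:
    """Symmetric mean nearest-point surface distance in mm.

    ``(sum_i d(G->P, i) + sum_i d(P->G, i)) / (N_G + N_P)`` over boundary
    voxel centers.  Either a ``spacing`` triple (axis-aligned grids) or a
    full ``affine`` may position the voxels in world space."""
    g, p = _as_bool(G), _as_bool(P)
    if g.shape != p.shape:
        raise ValueError(f"grid mismatch: {g.shape} vs {p.shape}")
    if not g.any() or not p.any():
        raise ValueError("empty segment: ASD undefined (missing label)")
    if affine is None:
        spacing = np.asarray(spacing if spacing is not None else (1.0, 1.0, 1.0), float)
        affine = np.diag(list(spacing) + [1.0])
    sg = surface_points(g, affine)
    sp = surface_points(p, affine)
    d_gp = cKDTree(sp.points_mm).query(sg.points_mm)[0]
    d_pg = cKDTree(sg.points_mm).query(sp.points_mm)[0]
    return float((d_gp.sum() + d_pg.sum()) / (len(sg) + len(sp)))


@dataclass
class EvalReport:
    """Per-label metric records for one (gt, pred) pair."""

    records: pd.DataFrame  # columns: label, dsc, asd_mm, gt_mm3, pred_mm3, excluded, missing
    subject: str = ""

    def included(self) -> pd.DataFrame:
        return self.records[~self.records["excluded"]]

    @property
    def overall_median_dsc(self) -> float:
        return float(self.included()["dsc"].median())

    @property
    def overall_median_asd(self) -> float:
        return float(self.included()["asd_mm"].median())

    def n_summarized(self) -> int:
        return int(len(self.included()))


def evaluate_labelmaps(
    gt: LabeledVolume,
    pred: LabeledVolume,
    policy: ExclusionPolicy | None = None,
    subject: str = "",
) -> EvalReport:
    """Per-label DSC/ASD with the missing-label and exclusion conventions.

    Labels missing from one map score DSC 0 / ASD NaN; labels absent from
    both maps are dropped entirely.  Excluded labels are computed but
    flagged and left out of summaries."""
    if gt.shape != pred.shape:
        raise ValueError(f"grid mismatch: {gt.shape} vs {pred.shape}")
    policy = policy or ExclusionPolicy()
    labels = sorted(set(gt.present_labels()) | set(pred.present_labels()) | set(gt.lut))
    vox = gt.voxel_volume
    rows = []
    for lab in labels:
        g = gt.data == lab
        p = pred.data == lab
        ng, np_ = int(g.sum()), int(p.sum())
        if ng == 0 and np_ == 0:
            continue  # absent from both: not scored
        missing = ng == 0 or np_ == 0
        if missing:
            dsc, asd = 0.0, float("nan")
        else:
            dsc = dice_coefficient(g, p)
            asd = average_surface_distance(g, p, affine=gt.affine)
        rows.append({
            "label": lab,
            "dsc": dsc,
            "asd_mm": asd,
            "gt_mm3": ng * vox,
            "pred_mm3": np_ * vox,
            "excluded": lab in policy.ids,
            "missing": missing,
        })
    return EvalReport(pd.DataFrame(rows), subject=subject)


def label_volumes(seg: LabeledVolume) -> pd.Series:
    """Per-label volume in mm^3 (voxel count x voxel volume)."""
    vox = seg.voxel_volume
    ids, counts = np.unique(seg.data, return_counts=True)
    vols = {int(i): float(c * vox) for i, c in zip(ids, counts) if i != 0}
    for lab in seg.lut:
        vols.setdefault(int(lab), 0.0)
    return pd.Series(vols, name="volume_mm3").sort_index()


@dataclass
class VolumetryRecord:
    subject: str
    group: str
    roi_volumes_mm3: dict[int, float]
    tiv_mm3: float

    def __post_init__(self) -> None:
        if self.tiv_mm3 <= 0:
            raise ValueError("TIV must be positive")

    def normalized(self, roi: int) -> float:
        v = self.roi_volumes_mm3[roi] / self.tiv_mm3
        if not 0.0 <= v < 1.0:
            raise ValueError(f"normalized volume {v} outside (0, 1)")
        return v


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks
    for v in np.unique(pooled):
        sel = pooled == v
        if sel.sum() > 1:
            ranks[sel] = ranks[sel].mean()
    ra = ranks[: len(a)].sum()
    return ra - len(a) * (len(a) + 1) / 2


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p-value of the U statistic (two-sided)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    na = len(a)
    mu = na * len(b) / 2
    obs = abs(_mwu_statistic(a, b) - mu)
    count = 0
    total = 0
    idx = np.arange(len(pooled))
    for comb in combinations(idx, na):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        u = _mwu_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def group_volume_test(
    group_a: Sequence[VolumetryRecord],
    group_b: Sequence[VolumetryRecord],
    roi: int,
    n_comparisons: int = 1,
):
    """Rank-sum test on TIV-normalized ROI volumes with Bonferroni threshold.

    Exact permutation p-value when the enumeration is small (<= 20000
    splits); tie-corrected normal approximation otherwise.  Returns
    ``(U, p, corrected_threshold, significant)``."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    a = np.asarray([r.normalized(roi) for r in group_a], dtype=float)
    b = np.asarray([r.normalized(roi) for r in group_b], dtype=float)
    u = _mwu_statistic(a, b)
    threshold = 0.05 / n_comparisons

    if np.ptp(np.concatenate([a, b])) == 0:
        return u, 1.0, threshold, False  # degenerate: all values identical

    from math import comb

    if comb(len(a) + len(b), len(a)) <= 20000:
        p = _exact_two_sided_p(a, b)
    else:
        na, nb = len(a), len(b)
        pooled = np.concatenate([a, b])
        n = na + nb
        mu = na * nb / 2
        tie_term = 0.0
        for v in np.unique(pooled):
            t = int((pooled == v).sum())
            tie_term += t**3 - t
        sigma = np.sqrt(na * nb / 12 * ((n + 1) - tie_term / (n * (n - 1))))
        z = (u - mu - 0.5 * np.sign(u - mu)) / sigma  # continuity-corrected
        p = float(min(1.0, 2 * norm.sf(abs(z))))
    return u, float(p), threshold, bool(p < threshold)


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 10_000, alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(median, lo, hi): percentile bootstrap CI of the median."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan"), float("nan")
    med = float(np.median(values))
    if values.size == 1:
        return med, med, med
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return med, float(lo), float(hi)


def summarize_cohort(
    reports: Sequence[EvalReport], n_boot: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Per-label and overall median with bootstrap 95% CI across subjects.

    Rows: one per included label plus an ``overall`` row whose median is
    taken over each subject's included-label median."""
    if not reports:
        raise ValueError("no reports to summarize")
    frames = []
    for i, rep in enumerate(reports):
        df = rep.included().copy()
        df["subject"] = rep.subject or f"subject-{i}"
        frames.append(df)
    allrec = pd.concat(frames, ignore_index=True)

    rows = []
    for lab, grp in allrec.groupby("label"):
        d_med, d_lo, d_hi = bootstrap_median_ci(grp["dsc"].to_numpy(), n_boot, seed=seed)
        a_med, a_lo, a_hi = bootstrap_median_ci(grp["asd_mm"].to_numpy(), n_boot, seed=seed)
        rows.append({"label": lab, "dsc_median": d_med, "dsc_lo": d_lo, "dsc_hi": d_hi,
                     "asd_median": a_med, "asd_lo": a_lo, "asd_hi": a_hi,
                     "n_subjects": grp["subject"].nunique()})
    per_subject = allrec.groupby("subject").agg(dsc=("dsc", "median"),
                                                asd=("asd_mm", "median"))
    d_med, d_lo, d_hi = bootstrap_median_ci(per_subject["dsc"].to_numpy(), n_boot, seed=seed)
    a_med, a_lo, a_hi = bootstrap_median_ci(per_subject["asd"].to_numpy(), n_boot, seed=seed)
    rows.append({"label": "overall", "dsc_median": d_med, "dsc_lo": d_lo,
                 "dsc_hi": d_hi, "asd_median": a_med, "asd_lo": a_lo,
                 "asd_hi": a_hi, "n_subjects": per_subject.shape[0]})
    return pd.DataFrame(rows)
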