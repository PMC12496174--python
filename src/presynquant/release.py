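"""Synaptic-vesicle release quantification and gel densitometry.

The release metric per bouton is (Fmax - F0)/Fmax, where F0 and Fmax are
ROI intensities of the maximum projection before and after KCl
depolarization. Group comparison uses the tie-corrected Kruskal-Wallis H
with a chi-square approximation, optionally followed by Dunn pairwise tests
with Holm adjustment. Densitometry measures lane profiles (row sums of a
rectangular selection), band areas above a straight-line (chord) baseline,
and co-IP/IP ratios normalized so each control reads exactly 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import ImageStack, max_project

__all__ = [
    "BoutonMeasurement",
    "GroupComparison",
    "measure_boutons",
    "kruskal_wallis",
    "dunn_posthoc",
    "lane_profile",
    "band_auc",
    "band_ratio",
]


@dataclass
class BoutonMeasurement:
    roi: int
    f0: float
    fmax: float
    release_metric: float
    f_nh4cl: float | None = None
    negative_flag: bool = False

    @property
    def normalized_metric(self) -> float | None:
        """(Fmax - F0)/(F_NH4Cl - F0): extension metric using the total
        vesicle pool revealed by NH4Cl; not part of the published formula."""
        if self.f_nh4cl is None or self.f_nh4cl == self.f0:
            return None
        return (self.fmax - self.f0) / (self.f_nh4cl - self.f0)


@dataclass
class GroupComparison:
    group_labels: list[str]
    groups: list[np.ndarray]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = field(default=None)


def _roi_means(img: np.ndarray, labels: np.ndarray, aggregate: str) -> dict[int, float]:
    if labels.shape != img.shape:
        raise ValueError("ROI label map must match the image grid")
    out = {}
    for roi in np.unique(labels):
        if roi == 0:
            continue
        vals = img[labels == roi]
        out[int(roi)] = float(vals.max() if aggregate == "max" else vals.mean())
    return out


def measure_boutons(
    f0_stack: ImageStack,
    fmax_stack: ImageStack,
    rois: np.ndarray,
    nh4cl_stack: ImageStack | None = None,
    aggregate: str = "mean",
) -> list[BoutonMeasurement]:
    """Per-bouton F0, Fmax and release metric from a frame pair.

    ``rois`` is an integer label map (0 = background) on the shared grid.
    F0/Fmax are the ``aggregate`` ("mean", default, or "max") of the
    max-projected stack within each ROI. Boutons with Fmax <= 0 are dropped
    with a warning; negative metrics (e.g. photobleaching) are retained and
    flagged.
    """
    if f0_stack.shape != fmax_stack.shape:
        raise ValueError("F0 and Fmax stacks must share the grid")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    rois = np.asarray(rois)
    if rois.max(initial=0) > 0 and rois.shape != f0_stack.shape:
        raise ValueError("ROI outside image: label map grid mismatch")
    f0_img = max_project(f0_stack).values
    fmax_img = max_project(fmax_stack).values
    f0_vals = _roi_means(f0_img, rois, aggregate)
    fmax_vals = _roi_means(fmax_img, rois, aggregate)
    nh_vals = (
        _roi_means(max_project(nh4cl_stack).values, rois, aggregate)
        if nh4cl_stack is not None
        else {}
    )
    out: list[BoutonMeasurement] = []
    for roi in sorted(f0_vals):
        f0, fmax = f0_vals[roi], fmax_vals[roi]
        if fmax <= 0:
            warnings.warn(f"bouton {roi} dropped: Fmax <= 0")
            continue
        metric = (fmax - f0) / fmax
        out.append(
            BoutonMeasurement(
                roi=roi,
                f0=f0,
                fmax=fmax,
                release_metric=metric,
                f_nh4cl=nh_vals.get(roi),
                negative_flag=metric < 0,
            )
        )
    return out


def kruskal_wallis(groups: list, labels: list[str] | None = None) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H test with chi-square p-value.

    H = [12 / (N (N+1)) * sum R_i^2 / n_i - 3 (N+1)] / C with mid-ranks for
    ties and C = 1 - sum(t^3 - t)/(N^3 - N). When every pooled value is
    identical, H is defined as 0 and p as 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs n >= 1")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need total n >= 3")
    if np.all(pooled == pooled[0]):
        return GroupComparison(labels, groups, 0.0, 1.0)
    ranks = stats.rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    h = h / correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return GroupComparison(labels, groups, float(h), p)


def dunn_posthoc(comparison: GroupComparison) -> pd.DataFrame:
    """Dunn pairwise z-tests on mean ranks with Holm adjustment.

    The published figure reports pairwise significance without naming a post
    hoc test; Dunn-Holm is the package's documented choice.
    """
    groups = comparison.groups
    labels = comparison.group_labels
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z,
                     "p_raw": 2.0 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df["p_raw"].to_numpy())
    m = len(df)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df["p_raw"].iloc[idx])
        adjusted[idx] = min(1.0, running)
    df["p_holm"] = adjusted
    comparison.pairwise = df
    return df


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------


def lane_profile(img: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Summed intensity per row of a rectangular lane selection.

    ``rect`` is ``(row0, col0, height, width)`` in pixel coordinates.
    """
    r0, c0, height, width = rect
    arr = np.asarray(img, dtype=np.float64)
    if r0 < 0 or c0 < 0 or r0 + height > arr.shape[0] or c0 + width > arr.shape[1]:
        raise ValueError("lane rectangle outside image")
    return arr[r0 : r0 + height, c0 : c0 + width].sum(axis=1)


def band_auc(profile: np.ndarray, baseline_endpoints: tuple[int, int] | None = None) -> float:
    """Band area above a straight-line (chord) baseline.

    The chord joins the profile values at ``baseline_endpoints`` (defaults to
    the first and last rows of the profile), mirroring the ImageJ gel tool's
    "straight line drawn to close off the area under the curve"; negative
    excursions below the chord are clipped to zero.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty profile")
    i0, i1 = baseline_endpoints if baseline_endpoints is not None else (0, p.size - 1)
    if not (0 <= i0 < i1 <= p.size - 1):
        raise ValueError("invalid baseline endpoints")
    chord = np.interp(np.arange(p.size), [i0, i1], [p[i0], p[i1]])
    return float(np.clip(p - chord, 0, None)[i0 : i1 + 1].sum())


def band_ratio(
    coip_auc: float, ip_auc: float, control_pair: tuple[float, float]
) -> tuple[float, float]:
    """Co-IP/IP intensity ratio normalized to the non-stimulated control.

    Returns ``(control_ratio, treated_ratio)``; the control reads exactly
    1.0 by construction and the treated value is
    (coip/ip) / (coip_control/ip_control).
    """
    coip_c, ip_c = control_pair
    if ip_auc <= 0 or ip_c <= 0 or coip_c <= 0:
        raise ValueError("zero denominator in band ratio")
    return 1.0, (coip_auc / ip_auc) / (coip_c / ip_c)
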