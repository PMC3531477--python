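"""Centromeric spot segmentation, background-corrected intensities and
normalizations.

The core measurement takes, for each spot, the area and integrated
intensity of a selected region (A_s, I_s) and of a slightly enlarged
region (A_l, I_l), and subtracts the locally estimated diffuse signal:

    corrected = I_s - A_s * (I_l - I_s) / (A_l - A_s)

Adding a constant to every pixel cancels out of this expression, so the
measurement is invariant to uniform background.  Negative corrected
values are reported as-is and flagged rather than clamped, which keeps
the estimator linear for group statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.measure import label as cc_label
from skimage.morphology import disk


class DegenerateRegionError(ValueError):
    """Dilation failed to enlarge a region (A_l == A_s)."""


class EmptyCellError(ValueError):
    """Within-cell normalization attempted on a nonpositive total."""


@dataclass(frozen=True)
class SegmentationParams:
    """Automatic replacement for manual free-hand region selection."""

    smoothing_sigma: float = 1.0
    threshold_k: float = 5.0
    min_area: int = 4
    dilation_radius: int = 2


@dataclass(frozen=True)
class SpotRegion:
    """A segmented spot region and its enlarged superset."""

    area_selected: int  # A_s
    intensity_selected: float  # I_s
    area_enlarged: int  # A_l
    intensity_enlarged: float  # I_l
    nucleus_id: int = 0
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.area_enlarged > self.area_selected > 0:
            raise ValueError("region invariant violated: need A_l > A_s > 0")
        if not self.intensity_enlarged >= self.intensity_selected >= 0:
            raise ValueError("region invariant violated: need I_l >= I_s >= 0")


@dataclass
class CentromereMeasurement:
    corrected_intensity: float
    nucleus_id: int = 0
    chromosome_class: str = "unassigned"
    negative: bool = False
    relative_pct: Optional[float] = None
    normalized_au: Optional[float] = None


@dataclass(frozen=True)
class CellMeasurement:
    nucleus_id: int
    total_corrected_intensity: float
    ploidy: float
    per_genome_intensity: float


def corrected_intensity(region: SpotRegion) -> float:
    """Background-corrected integrated intensity of one spot region."""
    a_s, i_s = region.area_selected, region.intensity_selected
    a_l, i_l = region.area_enlarged, region.intensity_enlarged
    if a_l <= a_s:
        raise ValueError("A_l must exceed A_s (division-by-zero precondition)")
    value = i_s - a_s * (i_l - i_s) / (a_l - a_s)
    if value < 0:
        warnings.warn("negative corrected intensity (reported, not clamped)", stacklevel=2)
    return value


def segment_spots(
    gfp_image: np.ndarray,
    params: SegmentationParams | None = None,
    nucleus_labels: Optional[np.ndarray] = None,
) -> list[SpotRegion]:
    """Threshold-based spot segmentation.

    Spot regions are connected components of the smoothed image above
    ``median + threshold_k * robust_sd`` (robust sd = 1.4826 * MAD) with
    area >= ``min_area``; the enlarged region is a morphological dilation
    of the selected region by ``dilation_radius``.  Integrated intensities
    are measured on the raw (unsmoothed) image.  An image with no
    components yields an empty list.
    """
    params = params or SegmentationParams()
    img = np.asarray(gfp_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    smoothed = ndi.gaussian_filter(img, params.smoothing_sigma)
    med = float(np.median(smoothed))
    robust_sd = 1.4826 * float(np.median(np.abs(smoothed - med)))
    mask = smoothed > med + params.threshold_k * robust_sd
    labels, n = cc_label(mask, return_num=True, connectivity=2)
    if n == 0:
        return []

    selem = disk(params.dilation_radius)
    pad = params.dilation_radius
    regions: list[SpotRegion] = []
    objects = ndi.find_objects(labels)
    for idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        sel_local = labels[slc] == idx
        a_s = int(sel_local.sum())
        if a_s < params.min_area:
            continue
        rlo = max(slc[0].start - pad, 0)
        rhi = min(slc[0].stop + pad, img.shape[0])
        clo = max(slc[1].start - pad, 0)
        chi = min(slc[1].stop + pad, img.shape[1])
        window = (slice(rlo, rhi), slice(clo, chi))
        sel = labels[window] == idx
        enlarged = ndi.binary_dilation(sel, structure=selem)
        a_l = int(enlarged.sum())
        if a_l == a_s:
            raise DegenerateRegionError("degenerate region: dilation did not enlarge the selection")
        sub = img[window]
        i_s = float(sub[sel].sum())
        i_l = float(sub[enlarged].sum())
        rr, cc = np.nonzero(sel)
        centroid = (float(rr.mean()) + rlo, float(cc.mean()) + clo)
        nid = 0
        if nucleus_labels is not None:
            nid = int(nucleus_labels[int(round(centroid[0])), int(round(centroid[1]))])
        regions.append(
            SpotRegion(
                area_selected=a_s,
                intensity_selected=i_s,
                area_enlarged=a_l,
                intensity_enlarged=i_l,
                nucleus_id=nid,
                centroid=centroid,
            )
        )
    return regions


def cell_total(
    measurements: Sequence[CentromereMeasurement], nucleus_id: int, ploidy: float = 1.0
) -> CellMeasurement:
    """Sum corrected intensities of one nucleus and express per genome."""
    values = [m.corrected_intensity for m in measurements if m.nucleus_id == nucleus_id]
    if not values:
        raise KeyError(f"no measurements for nucleus_id {nucleus_id}")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    total = float(sum(values))
    return CellMeasurement(nucleus_id, total, ploidy, total / ploidy)


def normalize_within_cell(values: Sequence[float]) -> np.ndarray:
    """Relative intensities (%) summing to exactly 100 within one cell."""
    arr = np.asarray(values, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise EmptyCellError("empty-cell normalization error: nonpositive total")
    rel = 100.0 * arr / total
    # absorb the float rounding residual of the division so the within-cell
    # sum is exactly 100.0: coarse-correct the largest entry, then ulp-step
    # entries from largest to smallest (one-shot correction oscillates
    # because numpy's summation order is not sequential, and a single
    # entry's ulp grid can straddle the target)
    residual = 100.0 - rel.sum()
    if residual != 0.0:
        rel[int(np.argmax(rel))] += residual
    for j in np.argsort(rel)[::-1]:
        for _ in range(128):
            residual = 100.0 - rel.sum()
            if residual == 0.0:
                return rel
            stepped = np.nextafter(rel[j], np.inf if residual > 0 else -np.inf)
            rel[j] = stepped
            new_residual = 100.0 - rel.sum()
            if new_residual == 0.0:
                return rel
            if (new_residual > 0) != (residual > 0):
                break  # crossed the target: refine with a finer-ulp entry
    return rel


def normalize_to_control(values: Sequence[float], control_values: Sequence[float]) -> np.ndarray:
    """Rescale values so that the control-group mean maps to 100 a.u."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("empty control group")
    mean = control.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) * 100.0 / mean


def identify_intensity_outlier(values: Sequence[float], ratio_threshold: float = 1.5) -> Optional[int]:
    """Index of the dominant signal if it exceeds ``ratio_threshold`` times
    the median of the remaining values, else ``None``.

    The default threshold is chosen so a 2-fold elevated signal is always
    flagged while equal signals never are.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    i = int(np.argmax(arr))
    rest = np.delete(arr, i)
    if arr[i] > ratio_threshold * float(np.median(rest)):
        return i
    return None


def compare_groups(group_a: Sequence[float], group_b: Sequence[float]) -> dict[str, float]:
    """Fold change (mean_b / mean_a) and Welch two-sample t-test p value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    fold = b.mean() / a.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {"fold_change": float(fold), "p_value": p}


def assign_chromosomes(
    regions: Sequence[SpotRegion],
    dna_image: Optional[np.ndarray],
    dna_landmarks,
    distance_cap: float = 20.0,
) -> list[str]:
    """Label each region pair4 / X / A2or3 / Y / unassigned from DNA landmarks.

    Per nucleus: the region nearest the bright chromosome-4 DNA dot is the
    paired-4 spot; the region nearest the irregular intense X region is the
    X; each homogeneous autosome territory claims its two nearest regions;
    a single remaining region (the one without an intense DNA neighbour)
    is the Y.  Ties are broken by higher corrected intensity.  If the X and
    paired-4 landmarks point at the same (merged) region it is excluded as
    unassigned, and nuclei without landmarks are left fully unassigned.
    ``dna_image`` is accepted for interface symmetry; the decision uses the
    landmark table.
    """
    if hasattr(dna_landmarks, "itertuples"):  # DataFrame form
        landmarks = [
            (int(r.nucleus_id), str(r.landmark_class), (float(r.row), float(r.col)))
            for r in dna_landmarks.itertuples()
        ]
    else:
        landmarks = [(lm.nucleus_id, lm.landmark_class, lm.center) for lm in dna_landmarks]

    labels = ["unassigned"] * len(regions)
    nuclei = {r.nucleus_id for r in regions}
    for nid in nuclei:
        idxs = [i for i, r in enumerate(regions) if r.nucleus_id == nid]
        lms = [lm for lm in landmarks if lm[0] == nid]
        if not lms:
            continue

        def nearest(center, candidates):
            best, best_key = None, None
            for i in candidates:
                d = math.dist(regions[i].centroid, center)
                if d > distance_cap:
                    continue
                key = (d, -corrected_intensity(regions[i]))
                if best_key is None or key < best_key:
                    best, best_key = i, key
            return best

        claimed: set[int] = set()
        p4 = x = None
        for _, cls, center in lms:
            if cls == "bright_dot_chr4":
                p4 = nearest(center, idxs)
            elif cls == "irregular_X_region":
                x = nearest(center, idxs)
        if p4 is not None and p4 == x:
            # merged X + paired-4 cluster: excluded from per-chromosome analysis
            claimed.add(p4)
        else:
            if p4 is not None:
                labels[p4] = "pair4"
                claimed.add(p4)
            if x is not None and x not in claimed:
                labels[x] = "X"
                claimed.add(x)
        for _, cls, center in lms:
            if cls != "homogeneous_territory":
                continue
            for _ in range(2):
                i = nearest(center, [i for i in idxs if i not in claimed])
                if i is None:
                    break
                labels[i] = "A2or3"
                claimed.add(i)
        # the Y is the spot without an intense DNA neighbour: identified by
        # elimination, but only once the rest of the territory is resolved
        territory_resolved = p4 is not None and x is not None and p4 != x
        leftover = [i for i in idxs if i not in claimed]
        if territory_resolved and len(leftover) == 1:
            labels[leftover[0]] = "Y"
    return labels


def measurements_frame(
    regions: Sequence[SpotRegion], classes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Tabulate regions with corrected intensities (one row per spot)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, r in enumerate(regions):
            corr = corrected_intensity(r)
            rows.append(
                {
                    "nucleus_id": r.nucleus_id,
                    "chromosome_class": classes[i] if classes is not None else "unassigned",
                    "A_s": r.area_selected,
                    "I_s": r.intensity_selected,
                    "A_l": r.area_enlarged,
                    "I_l": r.intensity_enlarged,
                    "corrected": corr,
                    "negative": corr < 0,
                    "row": r.centroid[0],
                    "col": r.centroid[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "chromosome_class",
            "A_s",
            "I_s",
            "A_l",
            "I_l",
            "corrected",
            "negative",
            "row",
            "col",
        ],
    )
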