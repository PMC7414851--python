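"""Foci-per-nucleus quantification of proximity-ligation-assay images.

The counting pipeline mirrors the classic CellProfiler recipe: nuclei are
segmented from the DAPI channel (smooth, Otsu threshold, fill holes, label,
area filter); PLA foci are detected on the PLA channel (white top-hat
band-pass, robust threshold, label, maximum-size filter); each focus is
assigned to the nucleus containing its intensity-weighted centroid
(parent-child), foci outside all nuclei are excluded; per-nucleus counts
per condition are compared with the two-sided Mann-Whitney rank-sum test.

For sequential (two-round) PLA the module also estimates the rigid drift
between rounds from the DAPI channel (translation by phase correlation,
rotation by an angular grid search with golden-section refinement) and
scores focus overlap between registered rounds against a within-nucleus
permutation null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology
from skimage.registration import phase_cross_correlation

from .profiles import mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = [
    "Segmentation",
    "RigidTransform",
    "segment_nuclei",
    "detect_foci",
    "assign_foci",
    "count_foci_per_nucleus",
    "compare_conditions",
    "register_rounds",
    "overlap_fraction",
]


@dataclass
class Segmentation:
    """Labelled nucleus masks plus per-nucleus records."""

    labels: np.ndarray                  # int image; 0 = background
    records: pd.DataFrame               # nucleus_id, cy, cx, area

    @property
    def n_nuclei(self) -> int:
        return len(self.records)


@dataclass
class RigidTransform:
    """Rigid drift between imaging rounds: rotate by ``angle_deg`` about the
    image centre, then translate by (dy, dx) pixels — the transform that
    takes round 1 onto round 2."""

    dy: float
    dx: float
    angle_deg: float
    score: float = float("nan")         # Pearson corr after alignment
    reliable: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dy) and math.isfinite(self.dx)
                and math.isfinite(self.angle_deg)):
            raise ValueError("non-finite transform")
        if abs(self.angle_deg) >= 45:
            raise ValueError("rotation beyond the +/-45 degree drift bound")


def segment_nuclei(dapi: np.ndarray, min_area: int = 200,
                   max_area: int | None = None,
                   smooth_sigma: float = 2.0) -> Segmentation:
    """Segment nuclei from a single-channel DAPI image.

    Gaussian smoothing -> Otsu global threshold -> hole filling ->
    connected components -> area filter.  Deterministic; an empty or
    signal-free image yields zero nuclei.
    """
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.size == 0 or np.ptp(img) == 0:
        return Segmentation(labels=np.zeros(img.shape, dtype=int),
                            records=_empty_records())
    sm = ndimage.gaussian_filter(img, smooth_sigma)
    thr = filters.threshold_otsu(sm)
    # Otsu always splits, even pure noise; demand that the threshold sits
    # clearly above the background noise floor before accepting foreground
    med = np.median(sm)
    sigma_est = 1.4826 * np.median(np.abs(sm - med))
    if thr - med < 4.0 * max(sigma_est, 1e-12):
        return Segmentation(labels=np.zeros(img.shape, dtype=int),
                            records=_empty_records())
    fg = ndimage.binary_fill_holes(sm > thr)
    labels, _ = ndimage.label(fg)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 1
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        if max_area is not None and rp.area > max_area:
            continue
        keep[rp.label] = next_id
        rows.append({"nucleus_id": next_id, "cy": rp.centroid[0],
                     "cx": rp.centroid[1], "area": int(rp.area)})
        next_id += 1
    relabelled = keep[labels]
    records = pd.DataFrame(rows) if rows else _empty_records()
    return Segmentation(labels=relabelled, records=records)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=["nucleus_id", "cy", "cx", "area"])


def detect_foci(pla: np.ndarray, max_area: int = 50, tophat_radius: int = 4,
                n_sigma: float = 6.0, min_area: int = 2) -> pd.DataFrame:
    """Detect diffraction-limited foci on a single-channel PLA image.

    A white top-hat (disk of ``tophat_radius``) removes background larger
    than a focus; pixels above a robust noise threshold (median +
    ``n_sigma`` * 1.4826 * MAD of the filtered image) are labelled, and
    components larger than ``max_area`` pixels (or smaller than
    ``min_area``, single-pixel noise) are discarded.  Centroids are
    intensity-weighted on the original image.

    Returns a DataFrame with ``focus_id, cy, cx, area``.
    """
    img = np.asarray(pla, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.size == 0:
        return _empty_foci()
    th = morphology.white_tophat(img, morphology.disk(tophat_radius))
    med = np.median(th)
    mad = np.median(np.abs(th - med))
    thr = med + n_sigma * 1.4826 * max(mad, 1e-12)
    mask = th > thr
    labels, n = ndimage.label(mask)
    rows = []
    fid = 1
    for rp in measure.regionprops(labels, intensity_image=img):
        if rp.area > max_area or rp.area < min_area:
            continue
        cy, cx = rp.centroid_weighted
        rows.append({"focus_id": fid, "cy": float(cy), "cx": float(cx),
                     "area": int(rp.area)})
        fid += 1
    return pd.DataFrame(rows) if rows else _empty_foci()


def _empty_foci() -> pd.DataFrame:
    return pd.DataFrame(columns=["focus_id", "cy", "cx", "area"])


def assign_foci(foci: pd.DataFrame, seg: Segmentation) -> pd.DataFrame:
    """Parent-child assignment: a focus belongs to the nucleus whose mask
    contains its centroid; foci outside all nuclei get parent 0 and are
    excluded from counts."""
    foci = foci.copy()
    if foci.empty:
        foci["parent"] = pd.Series(dtype=int)
        return foci
    ys = np.clip(np.round(foci["cy"]).astype(int), 0, seg.labels.shape[0] - 1)
    xs = np.clip(np.round(foci["cx"]).astype(int), 0, seg.labels.shape[1] - 1)
    foci["parent"] = seg.labels[ys, xs]
    return foci


def count_foci_per_nucleus(foci: pd.DataFrame, seg: Segmentation) -> pd.DataFrame:
    """Per-nucleus focus counts (zeros included for focus-free nuclei)."""
    assigned = assign_foci(foci, seg)
    counts = pd.DataFrame({"nucleus_id": seg.records["nucleus_id"].astype(int)})
    if assigned.empty:
        counts["count"] = 0
        return counts
    per = assigned[assigned["parent"] > 0].groupby("parent").size()
    counts["count"] = counts["nucleus_id"].map(per).fillna(0).astype(int)
    return counts


def compare_conditions(counts_a, counts_b, label_a: str = "a",
                       label_b: str = "b", ns_threshold: float = 0.05,
                       sig_threshold: float = 0.001) -> dict:
    """Compare per-nucleus focus counts between two conditions.

    Reports the fold ratio of means (a over b), the two-sided Mann-Whitney
    U and p, and a significance label: "significant" below
    ``sig_threshold``, "NS" above ``ns_threshold``, otherwise the raw p is
    the label.  The raw p is always reported regardless of label.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 nuclei per condition")
    u, p = mann_whitney_u(a, b)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = mean_a / mean_b if mean_b > 0 else float("inf")
    if p < sig_threshold:
        label = "significant"
    elif p > ns_threshold:
        label = "NS"
    else:
        label = f"p={p:.3g}"
    return {"condition_a": label_a, "condition_b": label_b,
            "mean_a": mean_a, "mean_b": mean_b, "n_a": int(a.size),
            "n_b": int(b.size), "fold_ratio": float(ratio), "U": float(u),
            "p_value": float(p), "label": label}


# ---------------------------------------------------------------------------
# sequential-round registration

def _project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of anything down to 2-D."""
    img = np.asarray(stack, dtype=float)
    while img.ndim > 2:
        img = img.max(axis=0)
    return img


def _corr_and_shift(ref: np.ndarray, mov: np.ndarray,
                    upsample: int = 50) -> tuple[float, tuple[float, float]]:
    """Best translation of ``mov`` onto ``ref`` and the Pearson correlation
    after applying it."""
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample,
                                          normalization=None)
    aligned = ndimage.shift(mov, shift, order=1, mode="constant", cval=0.0)
    r = np.corrcoef(ref.ravel(), aligned.ravel())[0, 1]
    return float(r), (float(shift[0]), float(shift[1]))


def register_rounds(dapi_round1: np.ndarray, dapi_round2: np.ndarray,
                    angle_range: float = 20.0, angle_step: float = 2.0,
                    min_score: float = 0.2) -> RigidTransform:
    """Estimate the rigid drift taking round 1 onto round 2.

    Returns (dy, dx, angle) such that rotating round 1 by ``angle`` about
    the image centre and shifting by (dy, dx) reproduces round 2 — i.e. the
    same parametrisation the simulator applies, so ground-truth transforms
    are recovered directly and correction of round 2 is the inverse
    transform.

    Translation comes from the phase-correlation peak; rotation from a
    coarse angular grid followed by golden-section refinement of the
    post-alignment correlation.  A best correlation below ``min_score``
    flags the result unreliable.
    """
    ref = _project(dapi_round1)
    mov = _project(dapi_round2)
    if ref.shape != mov.shape:
        raise ValueError("rounds must share the same field and shape")

    def score(angle: float) -> tuple[float, tuple[float, float]]:
        # undo candidate rotation on round 2, then find residual translation
        un = ndimage.rotate(mov, -angle, reshape=False, order=1,
                            mode="constant", cval=0.0) if angle else mov
        r, shift = _corr_and_shift(ref, un)
        return r, shift

    angles = np.arange(-angle_range, angle_range + 1e-9, angle_step)
    best_a, best_r = 0.0, -np.inf
    for a in angles:
        r, _ = score(float(a))
        if r > best_r:
            best_a, best_r = float(a), r
    # golden-section refinement around the best grid angle
    lo, hi = best_a - angle_step, best_a + angle_step
    phi = (math.sqrt(5) - 1) / 2
    c, d = hi - phi * (hi - lo), lo + phi * (hi - lo)
    rc, _ = score(c)
    rd, _ = score(d)
    while hi - lo > 0.02:
        if rc > rd:
            hi, d, rd = d, c, rc
            c = hi - phi * (hi - lo)
            rc, _ = score(c)
        else:
            lo, c, rc = c, d, rd
            d = lo + phi * (hi - lo)
            rd, _ = score(d)
    angle = (lo + hi) / 2
    # with the angle fixed, measure the residual translation in the round-2
    # frame: round2 = shift(rotate(round1, angle), d), so the phase-corr
    # shift registering round2 onto rotate(round1, angle) is -d
    ref_rot = ndimage.rotate(ref, angle, reshape=False, order=1,
                             mode="constant", cval=0.0) if angle else ref
    r_final, shift = _corr_and_shift(ref_rot, mov)
    dy, dx = -shift[0], -shift[1]
    reliable = r_final >= min_score
    if not reliable:
        logger.warning("register_rounds: alignment correlation %.3f below "
                       "floor %.2f; transform flagged unreliable",
                       r_final, min_score)
    return RigidTransform(dy=dy, dx=dx, angle_deg=angle, score=r_final,
                          reliable=reliable)


def transform_points(points: np.ndarray, transform: RigidTransform,
                     shape: tuple[int, int], inverse: bool = False) -> np.ndarray:
    """Apply (or invert) a rigid transform to (y, x) point coordinates.

    Forward maps round-1 coordinates into the round-2 frame; ``inverse``
    maps round-2 detections back into the round-1 frame for overlap
    scoring.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    th = math.radians(transform.angle_deg)
    # in (y, x) coordinates the image rotation moves a point at offset
    # (y, x) from the centre to (y cos - x sin, y sin + x cos)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    centre = np.array([cy, cx])
    t = np.array([transform.dy, transform.dx])
    if not inverse:
        return (pts - centre) @ rot.T + centre + t
    return (pts - centre - t) @ rot + centre


def overlap_fraction(foci1: pd.DataFrame, foci2: pd.DataFrame, radius: float,
                     seg: Segmentation | None = None,
                     n_permutations: int = 200, seed: int = 0) -> tuple[float, float]:
    """Fraction of foci matched between two registered rounds, with a
    permutation p-value.

    Foci are matched greedily by ascending centroid distance, each focus
    used at most once, matches only within ``radius`` pixels; the fraction
    is matches / min(n1, n2).  The null re-places the round-2 foci
    uniformly within their parent nuclei ``n_permutations`` times (requires
    ``seg`` and a ``parent`` column); p is the fraction of permutations
    with at least the observed number of matches.
    """
    n1, n2 = len(foci1), len(foci2)
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    p1 = foci1[["cy", "cx"]].to_numpy(dtype=float)
    p2 = foci2[["cy", "cx"]].to_numpy(dtype=float)
    obs = _greedy_matches(p1, p2, radius)
    frac = obs / min(n1, n2)
    if seg is None or "parent" not in foci2.columns:
        return float(frac), float("nan")
    rng = np.random.default_rng(seed)
    null_ge = 0
    parents = foci2["parent"].to_numpy()
    nuc_pix = {int(nid): np.column_stack(np.nonzero(seg.labels == nid))
               for nid in np.unique(parents) if nid > 0}
    inside = parents > 0
    for _ in range(n_permutations):
        q2 = p2.copy()
        for k in np.nonzero(inside)[0]:
            pix = nuc_pix[int(parents[k])]
            q2[k] = pix[rng.integers(len(pix))] + rng.random(2) - 0.5
        if _greedy_matches(p1, q2, radius) >= obs:
            null_ge += 1
    return float(frac), null_ge / n_permutations


def _greedy_matches(p1: np.ndarray, p2: np.ndarray, radius: float) -> int:
    d = np.sqrt(((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2))
    pairs = np.argwhere(d <= radius)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used1: set[int] = set()
    used2: set[int] = set()
    matches = 0
    for i, j in pairs[order]:
        if i in used1 or j in used2:
            continue
        used1.add(int(i))
        used2.add(int(j))
        matches += 1
    return matches
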