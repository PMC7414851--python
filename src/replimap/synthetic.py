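"""Seeded generators for genomes, ChIP counts, contact matrices and PLA images.

Each generator is a pure function of its config (including the seed) and
emulates the statistical structure the downstream analyses assume:

* blocky A/B compartments with a replication-timing (RT) track whose sign
  follows the compartment (A early/positive, B late/negative);
* histone-mark tag counts favouring A (H3K4me3) or B (H3K9me3) windows;
* ChIP tag counts multinomially biased along RT — positive bias emulates an
  early-replicating, DONSON-like factor, negative bias a late-replicating,
  FANCM-like factor, zero bias an input library;
* distance-decaying, compartment-checkered Hi-C contact matrices;
* two-channel nucleus/foci images with Poisson focus counts per nucleus.

Ground truth (labels, true counts, positions, applied transforms) is
returned alongside every simulated object so recovery can be asserted
exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import child_rng
from .compartments import ContactMatrix
from .genomic_io import WindowGrid, make_windows

logger = logging.getLogger(__name__)

__all__ = [
    "SimGenomeConfig",
    "SimChipConfig",
    "SimPlaConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_chip_counts",
    "simulate_contact_matrix",
    "simulate_pla_images",
    "shift_and_rotate_stack",
]

# fixed RNG stream numbers per generator role (never renumber)
_STREAM_BLOCKS = 0
_STREAM_RT = 1
_STREAM_K4 = 2
_STREAM_K9 = 3
_STREAM_CHIP = 4
_STREAM_HIC = 5
_STREAM_PLA = 6


@dataclass(frozen=True)
class SimGenomeConfig:
    """Parameters of the simulated genome.

    ``compartment_mean_block`` is the expected A/B run length in bp;
    ``rt_amplitude`` the mean |RT| (RT = log2(Early/Late)) in each
    compartment; ``mark_contrast`` the fold preference of each histone mark
    for its favoured compartment.
    """

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chrS1": 10_000_000})
    window_width: int = 50_000
    compartment_mean_block: int = 500_000
    frac_A: float = 0.5
    rt_amplitude: float = 1.5
    rt_noise_sd: float = 0.5
    mark_contrast: float = 4.0
    mark_total_tags: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not 0 < self.frac_A < 1:
            raise ValueError("frac_A must be in (0, 1)")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        for chrom, length in self.chrom_sizes.items():
            if length <= self.window_width:
                raise ValueError(
                    f"chromosome {chrom!r} length {length} must exceed the "
                    f"window width {self.window_width}")


@dataclass(frozen=True)
class SimChipConfig:
    """Multinomial ChIP tag model: ``p_i ∝ exp(bias_beta * RT_i)``.

    ``bias_beta > 0`` biases tags toward early-replicating windows
    (DONSON-like), ``< 0`` toward late (FANCM-like), ``0`` gives an
    unbiased input library.
    """

    total_tags: int = 1_000_000
    bias_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_tags <= 0:
            raise ValueError("total_tags must be positive")


@dataclass(frozen=True)
class SimPlaConfig:
    """PLA image simulation: Poisson foci inside non-overlapping nuclei.

    Foci are isotropic Gaussian spots; ``min_focus_separation`` keeps foci
    within a nucleus mutually resolvable (set 0 for pure uniform placement).
    """

    n_nuclei: int = 60
    lambda_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"early": 4.0, "late": 1.0})
    nucleus_radius_px: float = 18.0
    focus_sigma_px: float = 1.5
    image_shape: tuple[int, int] = (512, 512)
    noise_sd: float = 2.0
    nucleus_intensity: float = 200.0
    focus_amplitude: float = 60.0
    min_focus_separation: float = 8.0
    #: place the nuclei once and reuse them for every condition — the
    #: sequential-imaging case where the same field is photographed per round
    shared_nuclei: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.lambda_by_condition.values()):
            raise ValueError("all lambdas must be >= 0")
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")


@dataclass
class GroundTruth:
    """Known truth persisted alongside each simulated dataset."""

    compartment: np.ndarray | None = None       # 'A'/'B' per window
    rt_true: np.ndarray | None = None           # noise-free RT per window
    eigenvector_sign: np.ndarray | None = None  # +1 (A) / -1 (B) per bin
    foci: dict | None = None                    # condition -> per-nucleus info
    transform: tuple | None = None              # (dy, dx, angle_deg)

    def to_json(self, path: str | Path) -> None:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(asdict(self), default=conv,
                                         indent=2, sort_keys=True) + "\n")


def _compartment_labels(n_windows: int, mean_block_windows: float,
                        frac_A: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating A/B blocks with geometric lengths.

    Block-length means are split so the expected A fraction equals
    ``frac_A``: mean_A = 2*frac_A*m, mean_B = 2*(1-frac_A)*m.
    """
    mean_A = max(1.0, 2.0 * frac_A * mean_block_windows)
    mean_B = max(1.0, 2.0 * (1.0 - frac_A) * mean_block_windows)
    labels = np.empty(n_windows, dtype="<U1")
    state = "A" if rng.random() < frac_A else "B"
    i = 0
    while i < n_windows:
        mean = mean_A if state == "A" else mean_B
        run = rng.geometric(1.0 / mean)
        labels[i:i + run] = state
        i += run
        state = "B" if state == "A" else "A"
    return labels


def simulate_genome(cfg: SimGenomeConfig) -> tuple[WindowGrid, pd.DataFrame, GroundTruth]:
    """Simulate compartments, RT and histone-mark tag counts on a window grid.

    Returns the grid, a per-window table (``window_id, chrom, start, end,
    rt, h3k4me3, h3k9me3``) and the ground truth.  RT is ``+rt_amplitude``
    in A windows and ``-rt_amplitude`` in B, plus Gaussian noise; mark tag
    counts are multinomial with weight ``mark_contrast`` in the favoured
    compartment and 1 elsewhere.
    """
    grid = make_windows(cfg.chrom_sizes, cfg.window_width)
    n = len(grid)
    mean_block_windows = cfg.compartment_mean_block / cfg.window_width
    rng_blocks = child_rng(cfg.seed, _STREAM_BLOCKS)
    labels = np.concatenate([
        _compartment_labels(len(sub), mean_block_windows, cfg.frac_A, rng_blocks)
        for _, sub in grid.windows.groupby("chrom", sort=False)])
    sign = np.where(labels == "A", 1.0, -1.0)
    rt_true = cfg.rt_amplitude * sign
    rng_rt = child_rng(cfg.seed, _STREAM_RT)
    rt = rt_true + rng_rt.normal(0.0, cfg.rt_noise_sd, size=n)

    def mark_counts(favoured: str, stream: int) -> np.ndarray:
        w = np.where(labels == favoured, cfg.mark_contrast, 1.0)
        p = w / w.sum()
        return child_rng(cfg.seed, stream).multinomial(cfg.mark_total_tags, p)

    table = grid.windows.copy()
    table["rt"] = rt
    table["h3k4me3"] = mark_counts("A", _STREAM_K4)
    table["h3k9me3"] = mark_counts("B", _STREAM_K9)
    truth = GroundTruth(compartment=labels, rt_true=rt_true,
                        eigenvector_sign=sign.astype(int))
    return grid, table, truth


def simulate_chip_counts(rt: np.ndarray, cfg: SimChipConfig) -> np.ndarray:
    """Multinomial ChIP tag counts with log-linear RT bias.

    ``counts ~ Multinomial(total_tags, p)`` with ``p_i ∝ exp(bias_beta *
    RT_i)``; the counts sum to ``total_tags`` exactly.
    """
    rt = np.asarray(rt, dtype=float)
    if not np.isfinite(rt).all():
        raise ValueError("RT track contains non-finite values")
    logw = cfg.bias_beta * rt
    logw -= logw.max()  # numerical stability
    p = np.exp(logw)
    p /= p.sum()
    rng = child_rng(cfg.seed, _STREAM_CHIP)
    return rng.multinomial(cfg.total_tags, p)


def simulate_contact_matrix(labels: np.ndarray, decay_exponent: float = 1.0,
                            same_compartment_boost: float = 1.0,
                            total_contacts: int = 2_000_000, seed: int = 0,
                            bin_width: int = 50_000,
                            chrom: str = "chrS1") -> ContactMatrix:
    """Poisson contact matrix with distance decay and compartment checkering.

    Expected intensity at ``(i, j)`` is proportional to
    ``max(|i-j|, 1)^(-decay_exponent) * (1 + boost * [label_i == label_j])``,
    scaled so the expected total equals ``total_contacts``; the upper
    triangle is Poisson-sampled and mirrored, so the output is symmetric by
    construction.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 bins")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.maximum(np.abs(i - j), 1).astype(float)
    same = (labels[:, None] == labels[None, :])
    lam = d ** (-decay_exponent) * (1.0 + same_compartment_boost * same)
    iu = np.triu_indices(n)
    lam_u = lam[iu]
    lam_u = lam_u / lam_u.sum() * total_contacts
    rng = child_rng(seed, _STREAM_HIC)
    counts_u = rng.poisson(lam_u).astype(float)
    M = np.zeros((n, n))
    M[iu] = counts_u
    M = M + np.triu(M, 1).T
    return ContactMatrix(counts=M, bin_width=bin_width, chrom=chrom)


# ---------------------------------------------------------------------------
# PLA image simulation

def _place_nuclei(cfg: SimPlaConfig, rng: np.random.Generator,
                  max_attempts: int = 20_000) -> np.ndarray:
    """Dart-throw non-overlapping nucleus centres; raises if packing fails."""
    h, w = cfg.image_shape
    r = cfg.nucleus_radius_px
    margin = r + 2
    min_d2 = (2 * r + 4) ** 2
    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < cfg.n_nuclei:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei of "
                f"radius {r} in a {h}x{w} image after {max_attempts} attempts")
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_d2 for y, x in centres):
            centres.append((cy, cx))
    return np.array(centres)


def _place_foci(k: int, centre: tuple[float, float], radius: float,
                min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions in a disk, rejection-sampled for mutual separation."""
    pts: list[tuple[float, float]] = []
    for _ in range(k):
        for _try in range(200):
            rho = radius * math.sqrt(rng.random())
            th = rng.uniform(0, 2 * math.pi)
            y = centre[0] + rho * math.sin(th)
            x = centre[1] + rho * math.cos(th)
            if all((y - py) ** 2 + (x - px) ** 2 >= min_sep ** 2 for py, px in pts):
                break
        else:
            logger.warning("focus separation %.1f px not achievable; placing anyway",
                           min_sep)
        pts.append((y, x))
    return np.array(pts).reshape(-1, 2)


def simulate_pla_images(cfg: SimPlaConfig) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render DAPI + PLA channel images for each condition.

    Nuclei are bright filled disks on the DAPI channel; PLA foci are
    Gaussian spots at uniform positions inside their nucleus, with
    per-nucleus counts ~ Poisson(lambda of the condition).  Gaussian read
    noise is added to both channels.

    Returns
    -------
    images : condition -> float array of shape (2, H, W), channel 0 = DAPI,
        channel 1 = PLA
    truth : per-condition nucleus centres, focus counts and focus positions
    """
    rng = child_rng(cfg.seed, _STREAM_PLA)
    h, w = cfg.image_shape
    images: dict[str, np.ndarray] = {}
    truth_foci: dict[str, dict] = {}
    # focus placement margin keeps the spot's mass inside the nucleus disk
    inner_r = max(cfg.nucleus_radius_px - 3.0 * cfg.focus_sigma_px, 1.0)

    def _patch(cy: float, cx: float, half: int):
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        return (slice(y0, y1), slice(x0, x1)), yy, xx

    shared_centres = _place_nuclei(cfg, rng) if cfg.shared_nuclei else None
    for cond, lam in cfg.lambda_by_condition.items():
        centres = shared_centres if shared_centres is not None \
            else _place_nuclei(cfg, rng)
        dapi = np.zeros((h, w))
        pla = np.zeros((h, w))
        counts = []
        foci_all = []
        r_nuc = cfg.nucleus_radius_px
        half_nuc = int(math.ceil(r_nuc)) + 2
        half_foc = int(math.ceil(5 * cfg.focus_sigma_px)) + 1
        for cy, cx in centres:
            sl, yy, xx = _patch(cy, cx, half_nuc)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_nuc ** 2
            dapi[sl][disk] = cfg.nucleus_intensity
            k = int(rng.poisson(lam))
            counts.append(k)
            pts = _place_foci(k, (cy, cx), inner_r,
                              cfg.min_focus_separation, rng)
            foci_all.append(pts.tolist())
            for fy, fx in pts:
                sl, yy, xx = _patch(fy, fx, half_foc)
                pla[sl] += cfg.focus_amplitude * np.exp(
                    -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * cfg.focus_sigma_px ** 2))
        dapi = dapi + rng.normal(0, cfg.noise_sd, size=(h, w))
        pla = pla + rng.normal(0, cfg.noise_sd, size=(h, w))
        images[cond] = np.stack([dapi, pla]).astype(np.float32)
        truth_foci[cond] = {
            "centres": centres.tolist(),
            "counts": counts,
            "foci": foci_all,
        }
    return images, GroundTruth(foci=truth_foci)


def shift_and_rotate_stack(stack: np.ndarray, dy: float, dx: float,
                           angle_deg: float, order: int = 1,
                           loss_warn_frac: float = 0.01) -> np.ndarray:
    """Rigid transform of an image or stack: rotate about the plane centre,
    then translate by (dy, dx).

    Works on 2-D images, (C, H, W) stacks, or (Z, C, H, W); the transform is
    applied plane-wise in (H, W).  Interpolation is spline of the given
    order (default bilinear).  If more than ``loss_warn_frac`` of total
    intensity leaves the frame, a warning reports the out-of-frame loss.
    """
    stack = np.asarray(stack, dtype=float)
    planes = stack.reshape(-1, *stack.shape[-2:])
    out = np.empty_like(planes)
    for k, img in enumerate(planes):
        t = img
        if angle_deg != 0:
            t = ndimage.rotate(t, angle_deg, reshape=False, order=order,
                               mode="constant", cval=0.0)
        if dy != 0 or dx != 0:
            t = ndimage.shift(t, (dy, dx), order=order, mode="constant", cval=0.0)
        out[k] = t
    before = float(np.abs(planes).sum())
    after = float(np.abs(out).sum())
    if before > 0 and (before - after) / before > loss_warn_frac:
        logger.warning("shift_and_rotate_stack: %.1f%% of intensity moved "
                       "out of frame", 100 * (before - after) / before)
    return out.reshape(stack.shape)
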