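"""Genome coordinate model, text-format I/O, and window binning.

All coordinates are 0-based, half-open (BED dialect), for chrom.sizes,
bedGraph and BED alike.  The analysis unit is the :class:`WindowGrid` of
equal-width windows tiling each chromosome from position 0; the terminal
partial window is dropped by default so that every retained window has
exactly the same width (per-window normalisations and quantile schemes
assume equal widths).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "IntervalTrack",
    "make_windows",
    "bin_track_mean",
    "bin_tag_counts",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_window_table",
    "write_window_table",
]


@dataclass(frozen=True)
class WindowGrid:
    """Ordered equal-width genomic windows.

    Attributes
    ----------
    windows
        DataFrame with columns ``chrom``, ``start``, ``end``, ``window_id``.
        ``window_id`` is dense ``0..n-1`` in file order; within a chromosome
        windows tile contiguously from 0.
    width
        Window width in bp.
    chrom_sizes
        Chromosome lengths the grid was built from.
    n_dropped_bp
        Total bp discarded as terminal partial windows.
    """

    windows: pd.DataFrame
    width: int
    chrom_sizes: dict = field(default_factory=dict)
    n_dropped_bp: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_index(self, chrom: str, pos: int) -> int:
        """window_id containing position ``pos`` on ``chrom``, or -1."""
        sub = self.windows[self.windows["chrom"] == chrom]
        if sub.empty:
            return -1
        i = pos // self.width
        if i >= len(sub):
            return -1
        return int(sub["window_id"].iloc[i])

    def to_bed(self) -> pd.DataFrame:
        return self.windows[["chrom", "start", "end", "window_id"]].copy()


@dataclass(frozen=True)
class IntervalTrack:
    """Per-interval score track (bedGraph semantics, 0-based half-open)."""

    intervals: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["end"] < df["start"]).any():
            raise ValueError("interval with negative length")

    def __len__(self) -> int:
        return len(self.intervals)


def make_windows(chrom_sizes: Mapping[str, int], width: int = 50_000,
                 keep_partial: bool = False) -> WindowGrid:
    """Tile each chromosome with equal-width windows from position 0.

    The default 50-kb width is the grid on which all downstream RT,
    eigenvector and coverage statistics are computed.  A terminal window
    shorter than ``width`` is dropped unless ``keep_partial`` is set; the
    dropped bp count is logged and recorded on the grid.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    rows = []
    dropped = 0
    wid = 0
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        n_full, rem = divmod(length, width)
        for i in range(n_full):
            rows.append((chrom, i * width, (i + 1) * width, wid))
            wid += 1
        if rem:
            if keep_partial:
                rows.append((chrom, n_full * width, length, wid))
                wid += 1
            else:
                dropped += rem
    if dropped:
        logger.info("make_windows: dropped %d bp of terminal partial windows", dropped)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id"])
    return WindowGrid(windows=df, width=width,
                      chrom_sizes=dict(chrom_sizes), n_dropped_bp=dropped)


def bin_track_mean(track: IntervalTrack, grid: WindowGrid) -> np.ndarray:
    """Coverage-length-weighted mean of a score track per window.

    Each interval contributes its value weighted by the number of bases it
    overlaps each window; windows with no overlapping interval are NaN
    (missing, never silently zero).
    """
    n = len(grid)
    num = np.zeros(n)
    den = np.zeros(n)
    gw = grid.windows
    width = grid.width
    # per-chromosome window_id offset (windows tile contiguously from 0)
    offsets = {}
    counts = {}
    for chrom, sub in gw.groupby("chrom", sort=False):
        offsets[chrom] = int(sub["window_id"].iloc[0])
        counts[chrom] = len(sub)
    for chrom, sub in track.intervals.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        limit = grid.chrom_sizes.get(chrom)
        if limit is not None and (sub["end"] > limit).any():
            bad = sub[sub["end"] > limit].iloc[0]
            raise ValueError(
                f"interval {chrom}:{int(bad['start'])}-{int(bad['end'])} "
                f"exceeds chromosome end {limit}")
        off = offsets[chrom]
        nwin = counts[chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        for s, e, v in zip(starts, ends, vals):
            w0 = s // width
            w1 = (e - 1) // width if e > s else w0
            for w in range(w0, min(w1, nwin - 1) + 1):
                ws, we = w * width, (w + 1) * width
                ov = min(e, we) - max(s, ws)
                if ov > 0:
                    num[off + w] += v * ov
                    den[off + w] += ov
    out = np.full(n, np.nan)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def bin_tag_counts(tags: pd.DataFrame, grid: WindowGrid) -> tuple[np.ndarray, int]:
    """Count tags per window by fragment-midpoint assignment.

    Each tag is assigned to the single window containing the midpoint of its
    interval, so assigned + discarded always equals the input tag count
    (tags whose midpoint falls in a dropped terminal remainder, or on an
    unknown chromosome, are discarded and counted).

    Parameters
    ----------
    tags
        DataFrame with ``chrom``, ``start``, ``end`` columns (BED3).

    Returns
    -------
    counts, n_discarded
    """
    n = len(grid)
    counts = np.zeros(n, dtype=np.int64)
    discarded = 0
    if (tags["start"] < 0).any() or (tags["end"] < tags["start"]).any():
        bad = tags[(tags["start"] < 0) | (tags["end"] < tags["start"])].index[0]
        raise ValueError(f"malformed tag record at row {bad}")
    offsets = {}
    nwin = {}
    for chrom, sub in grid.windows.groupby("chrom", sort=False):
        offsets[chrom] = int(sub["window_id"].iloc[0])
        nwin[chrom] = len(sub)
    width = grid.width
    for chrom, sub in tags.groupby("chrom", sort=False):
        mids = ((sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2)
        if chrom not in offsets:
            discarded += len(mids)
            continue
        idx = mids // width
        ok = idx < nwin[chrom]
        discarded += int((~ok).sum())
        np.add.at(counts, offsets[chrom] + idx[ok], 1)
    if discarded:
        logger.info("bin_tag_counts: discarded %d of %d tags outside the grid",
                    discarded, len(tags))
    return counts, discarded


# ---------------------------------------------------------------------------
# text formats

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_bedgraph(path: str | Path) -> IntervalTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "value": float})
    return IntervalTrack(intervals=df)


def write_bedgraph(track: IntervalTrack | pd.DataFrame, path: str | Path) -> None:
    df = track.intervals if isinstance(track, IntervalTrack) else track
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED4; extra columns are dropped. Malformed lines raise with
    their line number."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED line has {len(parts)} fields, need >= 3")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
        name = parts[3] if len(parts) > 3 else "."
        rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_window_table(table: pd.DataFrame, path: str | Path,
                       metadata: dict | None = None) -> None:
    """Write a per-window table as TSV with a JSON sidecar of column metadata."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    meta = {"columns": list(table.columns)}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_window_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
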