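"""Per-window enrichment statistics and quantile coverage profiles.

This is the genomic half of the analysis: tag counts on equal-width windows
are scaled to tags per million (TPM), ChIP-over-input enrichment is the
log2 TPM ratio, enriched windows (enrichment strictly > 0) are compared
against size-matched random control windows via their replication-timing
distributions, and coverage is profiled across n = 25 quantiles of RT or
of the Hi-C compartment eigenvector (quantile 1 = latest / most-B,
quantile n = earliest / most-A).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSummary",
    "QuantileProfile",
    "EnrichmentSelection",
    "tpm_normalize",
    "compute_enrichment",
    "select_enriched_windows",
    "sample_matched_controls",
    "assign_quantiles",
    "quantile_coverage_profile",
    "violin_rt_summary",
    "mann_whitney_u",
    "trend_statistic",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Box-plot style summary: median, quartiles, 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mean: float
    n: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "DistributionSummary":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("no finite values to summarise")
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        return cls(median=float(med), q1=float(q1), q3=float(q3),
                   whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
                   mean=float(v.mean()), n=int(v.size))

    def as_dict(self) -> dict:
        return {"median": self.median, "q1": self.q1, "q3": self.q3,
                "whisker_lo": self.whisker_lo, "whisker_hi": self.whisker_hi,
                "mean": self.mean, "n": self.n}


@dataclass
class QuantileProfile:
    """Per-quantile coverage distributions for one sample and scheme."""

    scheme: str                 # "rt" or "eigenvector"
    sample: str
    n_quantiles: int
    summary: pd.DataFrame       # quantile, n, mean, median, q1, q3, whiskers
    members: dict = field(default_factory=dict)  # quantile -> window_id array

    def to_tsv(self, path) -> None:
        df = self.summary.copy()
        df.insert(0, "sample", self.sample)
        df.insert(0, "scheme", self.scheme)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class EnrichmentSelection:
    """Enriched windows of one sample plus matched random controls."""

    sample: str
    selected: np.ndarray
    controls: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.controls) != len(self.selected):
            raise ValueError("controls must match selected in number")


def tpm_normalize(counts: np.ndarray) -> np.ndarray:
    """Tags per million: counts scaled so the genome-wide sum is 10^6.

    Windows are equal-width so no length term enters.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total counts")
    return counts / total * 1e6


def compute_enrichment(chip_tpm: np.ndarray, input_tpm: np.ndarray,
                       pseudocount: float = 1.0) -> np.ndarray:
    """Per-window enrichment = log2((chip + c) / (input + c)) in TPM.

    The default pseudocount c = 1 TPM regularises empty windows; c = 0 is
    allowed only when both tracks are strictly positive.
    """
    chip = np.asarray(chip_tpm, dtype=float)
    inp = np.asarray(input_tpm, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError("ChIP and input tracks are on different grids")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and ((chip <= 0).any() or (inp <= 0).any()):
        raise ValueError("pseudocount 0 requires strictly positive tracks")
    return np.log2(chip + pseudocount) - np.log2(inp + pseudocount)


def select_enriched_windows(enrichment: np.ndarray) -> np.ndarray:
    """Window ids with enrichment strictly greater than zero."""
    e = np.asarray(enrichment, dtype=float)
    return np.where(e > 0)[0]


def sample_matched_controls(n_windows: int, k: int, seed: int,
                            exclude: np.ndarray | None = None) -> np.ndarray:
    """Draw k distinct control windows uniformly without replacement.

    By default every retained window is eligible (enriched windows are not
    excluded); pass ``exclude`` to remove a set of ids from the pool.
    """
    pool = np.arange(n_windows)
    if exclude is not None:
        pool = np.setdiff1d(pool, np.asarray(exclude))
    if k > len(pool):
        raise ValueError(f"cannot draw {k} controls from {len(pool)} windows")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=k, replace=False))


def assign_quantiles(values: np.ndarray, n: int = 25) -> np.ndarray:
    """Equal-count quantile labels 1..n, ascending in value.

    Windows are sorted ascending (ties broken by genomic order, i.e. input
    order, via a stable sort) and split into n contiguous bins whose sizes
    differ by at most one, any remainder going to the lowest quantiles.
    Label 1 holds the smallest values (latest RT / most-B).  Missing values
    get label 0 and are excluded from all profiles.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    m = int(finite.sum())
    if m < n:
        raise ValueError(f"need at least n={n} non-missing values, have {m}")
    labels = np.zeros(len(values), dtype=int)
    order = np.argsort(values[finite], kind="stable")
    q, r = divmod(m, n)
    sizes = np.full(n, q)
    sizes[:r] += 1
    ranks_to_label = np.repeat(np.arange(1, n + 1), sizes)
    lab_finite = np.empty(m, dtype=int)
    lab_finite[order] = ranks_to_label
    labels[finite] = lab_finite
    return labels


def quantile_coverage_profile(tpm: np.ndarray, labels: np.ndarray,
                              scheme: str = "rt",
                              sample: str = "sample") -> QuantileProfile:
    """Distribution of window TPM within each quantile.

    Reports the full box-plot summary plus the mean per quantile, ordered
    from quantile 1 (late / B) to n (early / A).
    """
    tpm = np.asarray(tpm, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_q = int(labels.max())
    rows = []
    members = {}
    for q in range(1, n_q + 1):
        ids = np.where(labels == q)[0]
        if ids.size == 0:
            raise ValueError(f"quantile {q} is empty")
        s = DistributionSummary.from_values(tpm[ids])
        members[q] = ids
        rows.append({"quantile": q, **s.as_dict()})
    summary = pd.DataFrame(rows)
    return QuantileProfile(scheme=scheme, sample=sample, n_quantiles=n_q,
                           summary=summary, members=members)


def violin_rt_summary(selected: np.ndarray, controls: np.ndarray,
                      rt: np.ndarray) -> dict:
    """RT distributions of enriched windows vs matched random controls.

    Returns both box summaries and the two-sided Mann-Whitney comparison,
    the statistic behind the violin-plot panels.
    """
    rt = np.asarray(rt, dtype=float)
    rt_sel = rt[np.asarray(selected, dtype=int)]
    rt_ctl = rt[np.asarray(controls, dtype=int)]
    rt_sel = rt_sel[np.isfinite(rt_sel)]
    rt_ctl = rt_ctl[np.isfinite(rt_ctl)]
    if rt_sel.size == 0 or rt_ctl.size == 0:
        raise ValueError("both sets must contain RT-scored windows")
    u, p = mann_whitney_u(rt_sel, rt_ctl)
    return {
        "selected": DistributionSummary.from_values(rt_sel).as_dict(),
        "controls": DistributionSummary.from_values(rt_ctl).as_dict(),
        "U": float(u),
        "p_value": float(p),
    }


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all assignments of the pooled
    sample, using midranks (so ties are handled naturally).

    p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    const = n * (n + 1) / 2.0
    us = np.fromiter(
        (sum(ranks[i] for i in comb) - const
         for comb in itertools.combinations(range(n + m), n)),
        dtype=float, count=math.comb(n + m, n))
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    ``U`` is the statistic of the first sample.  The exact branch
    enumerates every assignment of the pooled observations (valid with
    ties, via midranks) and is used when min(n, m) <= 8; larger samples use
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u, 1.0  # all observations identical
    if method == "auto":
        method = "exact" if min(n, m) <= 8 else "asymptotic"
    if method == "exact":
        return u, _exact_mwu_p(x, y, u)
    if method == "asymptotic":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return u, float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def trend_statistic(profile: QuantileProfile) -> tuple[float, bool]:
    """Spearman rho between quantile index and per-quantile mean coverage.

    +1 means coverage rises monotonically toward early-replicating / A
    quantiles, -1 toward late / B.  Constant means give rho = 0 with a
    flag.
    """
    means = profile.summary["mean"].to_numpy()
    if len(means) < 3:
        raise ValueError("need at least 3 quantiles")
    if np.ptp(means) == 0:
        logger.warning("trend_statistic: constant quantile means")
        return 0.0, True
    rho, _ = stats.spearmanr(np.arange(1, len(means) + 1), means)
    return float(rho), False
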