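"""A/B compartment eigenvector from a binned Hi-C contact matrix.

The chain is the standard one for coarse compartment calling: mask sparse
bins, Knight-Ruiz (KR) balance the symmetric count matrix, normalise for
genomic-distance decay (observed/expected), correlate bin profiles
(Pearson matrix), and take the first principal component.  The PC1 sign is
arbitrary, so :func:`orient_eigenvector` flips it against a reference track
(replication timing by convention) so that positive values mark the A
compartment — open, early-replicating chromatin — and negative values B.

Everything operates per chromosome: compartment eigenvectors are not
comparable across chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import pearson

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "EigenvectorTrack",
    "kr_balance",
    "observed_over_expected",
    "pearson_matrix",
    "compartment_eigenvector",
    "orient_eigenvector",
    "compartment_track",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_sparse_triplets",
    "write_sparse_triplets",
]

#: bins with fewer than this fraction of nonzero contacts are masked before
#: balancing; KR is unstable on near-empty rows.
DEFAULT_MIN_NONZERO_FRAC = 0.25


@dataclass
class ContactMatrix:
    """Binned symmetric intra-chromosomal contact counts.

    ``mask`` marks retained bins; all-zero and overly sparse rows are
    excluded before balancing (see :func:`sparse_bin_mask`).
    """

    counts: np.ndarray
    bin_width: int = 50_000
    chrom: str = "chr"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.counts, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(M, M.T):
            raise ValueError("contact matrix must be symmetric")
        if (M < 0).any():
            raise ValueError("contact matrix must be nonnegative")
        self.counts = M
        if self.mask is None:
            self.mask = sparse_bin_mask(M)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def sparse_bin_mask(M: np.ndarray,
                    min_nonzero_frac: float = DEFAULT_MIN_NONZERO_FRAC) -> np.ndarray:
    """Boolean mask of bins retained for balancing."""
    n = M.shape[0]
    nz_frac = (M > 0).sum(axis=0) / n
    mask = nz_frac >= min_nonzero_frac
    n_masked = int((~mask).sum())
    if n_masked:
        logger.info("masked %d/%d sparse bins (nonzero fraction < %.2f)",
                    n_masked, n, min_nonzero_frac)
    return mask


def kr_balance(matrix: ContactMatrix | np.ndarray, tol: float = 1e-12,
               max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Knight-Ruiz balancing of a symmetric nonnegative matrix.

    Finds a positive vector ``x`` such that ``diag(x) M diag(x)`` has equal
    row sums (normalised to 1) on retained bins, using the inner-outer
    Newton iteration of Knight & Ruiz with conjugate-gradient inner solves.
    If the iteration fails to converge, falls back to square-root "vanilla"
    coverage normalisation ``x_i = 1/sqrt(rowsum_i)`` with a warning.

    Returns
    -------
    x : full-length scaling vector, NaN on masked bins
    B : balanced matrix, NaN rows/cols on masked bins
    """
    if isinstance(matrix, ContactMatrix):
        M_full, mask = matrix.counts, matrix.mask
    else:
        M_full = np.asarray(matrix, dtype=float)
        mask = sparse_bin_mask(M_full)
    A = M_full[np.ix_(mask, mask)]
    n = A.shape[0]
    if n == 0:
        raise ValueError("no retained bins to balance")

    x_sub, converged = _kr_core(A, tol=tol, max_iter=max_iter)
    if not converged:
        logger.warning("KR balancing did not converge in %d iterations; "
                       "falling back to sqrt coverage normalisation", max_iter)
        rs = A.sum(axis=1)
        x_sub = 1.0 / np.sqrt(rs)
    # normalise so balanced row sums equal 1
    B_sub = A * np.outer(x_sub, x_sub)
    scale = B_sub.sum(axis=1).mean()
    x_sub = x_sub / np.sqrt(scale)
    B_sub = A * np.outer(x_sub, x_sub)

    N = M_full.shape[0]
    x = np.full(N, np.nan)
    x[mask] = x_sub
    B = np.full((N, N), np.nan)
    B[np.ix_(mask, mask)] = B_sub
    return x, B


def _kr_core(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Inner-outer Newton iteration for the KR fixed point diag(x)Ax = e,
    with conjugate-gradient inner solves and safeguarded step bounds
    (delta = 0.1, Delta = 3)."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rho_km1
    rold = rout
    outer = 0
    Z = p = None
    while rout > rt:
        outer += 1
        if outer > max_iter:
            return x, False
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        # safeguarded forcing-term update
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / res_norm)
    return x, True


def observed_over_expected(B: np.ndarray,
                           mask: np.ndarray | None = None) -> np.ndarray:
    """Divide each entry by the mean of its genomic-distance diagonal.

    Expected at distance ``d = |i-j|`` is the mean of ``B`` over retained
    pairs at that distance on the chromosome; distances with no retained
    pairs stay missing.
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if mask is None:
        mask = np.isfinite(B).any(axis=0)
    OE = np.full_like(B, np.nan)
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise ValueError("all bins masked")
    sub = B[np.ix_(idx, idx)]
    sub_oe = np.full_like(sub, np.nan)
    di = np.abs(idx[:, None] - idx[None, :])
    for d in np.unique(di):
        sel = di == d
        vals = sub[sel]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        exp = vals[finite].mean()
        if exp > 0:
            out = np.full(vals.shape, np.nan)
            out[finite] = vals[finite] / exp
            sub_oe[sel] = out
    OE[np.ix_(idx, idx)] = sub_oe
    return OE


def pearson_matrix(OE: np.ndarray, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of O/E row profiles.

    Returns the full-size correlation matrix (NaN on masked bins) and the
    possibly tightened retained-bin mask: rows with zero variance cannot be
    correlated and are dropped with a warning.
    """
    OE = np.asarray(OE, dtype=float)
    n = OE.shape[0]
    if mask is None:
        mask = np.isfinite(OE).any(axis=0)
    idx = np.where(mask)[0]
    if idx.size < 3:
        raise ValueError("need at least 3 retained bins")
    sub = OE[np.ix_(idx, idx)]
    # columns with any NaN (distances absent) are excluded from every row's
    # profile so all correlations use the same support
    col_ok = np.isfinite(sub).all(axis=0)
    prof = sub[:, col_ok]
    sd = prof.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("pearson_matrix: masking %d zero-variance bins",
                       int((~keep).sum()))
        idx = idx[keep]
        sub = OE[np.ix_(idx, idx)]
        col_ok = np.isfinite(sub).all(axis=0)
        prof = sub[:, col_ok]
    C = np.corrcoef(prof)
    np.fill_diagonal(C, 1.0)
    P = np.full((n, n), np.nan)
    P[np.ix_(idx, idx)] = C
    new_mask = np.zeros(n, dtype=bool)
    new_mask[idx] = True
    return P, new_mask


@dataclass
class EigenvectorTrack:
    """Per-bin compartment eigenvector; positive = A after orientation."""

    values: np.ndarray
    eigenvalue_share: float = float("nan")
    oriented: bool = False
    orientation_reference: str | None = None
    flags: list = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def compartment_eigenvector(P: np.ndarray, mask: np.ndarray | None = None,
                            degenerate_tol: float = 1e-8) -> EigenvectorTrack:
    """First principal component of the Pearson matrix (unoriented).

    The PC1 is the eigenvector, with the largest eigenvalue, of the
    column-centred covariance of ``P``; it is unit norm and per chromosome.
    The pre-orientation sign is fixed deterministically by making the
    largest-magnitude loading positive.  A near-degenerate top of the
    spectrum (top two eigenvalues within ``degenerate_tol`` relative) is
    flagged, as is a low explained-variance share (< 0.2: no compartment
    structure to speak of).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if mask is None:
        mask = np.isfinite(P).any(axis=0)
    idx = np.where(mask)[0]
    sub = P[np.ix_(idx, idx)]
    if not np.isfinite(sub).all():
        raise ValueError("Pearson matrix has non-finite entries on retained bins")
    X = sub - sub.mean(axis=0, keepdims=True)
    C = (X.T @ X) / max(len(idx) - 1, 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    v = evecs[:, 0]
    flags = []
    total = evals.sum()
    share = float(evals[0] / total) if total > 0 else 0.0
    if len(evals) > 1 and abs(evals[0] - evals[1]) <= degenerate_tol * max(abs(evals[0]), 1e-30):
        flags.append("degenerate_spectrum")
        logger.warning("top two eigenvalues nearly equal; PC1 direction unstable")
    if share < 0.2:
        flags.append("low_eigenvalue_share")
    # deterministic sign before orientation
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    values = np.full(n, np.nan)
    values[idx] = v
    return EigenvectorTrack(values=values, eigenvalue_share=share, flags=flags)


def orient_eigenvector(ev: EigenvectorTrack, reference: np.ndarray,
                       reference_name: str = "RT",
                       min_abs_corr: float = 0.05) -> EigenvectorTrack:
    """Orient PC1 so positive values align with the reference track.

    With replication timing as the reference this puts A (early) at
    positive values and B (late) at negative, the usual sign convention.
    A near-zero correlation leaves the sign unchanged and flags the track
    as ambiguous.
    """
    reference = np.asarray(reference, dtype=float)
    both = ev.mask & np.isfinite(reference)
    if both.sum() < 10:
        raise ValueError("reference defined on fewer than 10 retained bins")
    r = pearson(ev.values[both], reference[both])
    flags = list(ev.flags)
    values = ev.values
    if not np.isfinite(r) or abs(r) < min_abs_corr:
        flags.append("ambiguous_orientation")
        logger.warning("orientation ambiguous: |corr(ev, %s)| = %.3g < %.2f",
                       reference_name, abs(r), min_abs_corr)
    elif r < 0:
        values = -values
    return EigenvectorTrack(values=values, eigenvalue_share=ev.eigenvalue_share,
                            oriented=True, orientation_reference=reference_name,
                            flags=flags)


def compartment_track(matrix: ContactMatrix, reference: np.ndarray | None = None,
                      tol: float = 1e-12, max_iter: int = 100) -> EigenvectorTrack:
    """Full chain: KR balance -> O/E -> Pearson -> PC1 -> orient."""
    _, B = kr_balance(matrix, tol=tol, max_iter=max_iter)
    OE = observed_over_expected(B, mask=matrix.mask)
    P, mask = pearson_matrix(OE, mask=matrix.mask)
    ev = compartment_eigenvector(P, mask=mask)
    if reference is not None:
        ev = orient_eigenvector(ev, reference)
    return ev


# ---------------------------------------------------------------------------
# matrix text I/O

def read_dense_matrix(path: str | Path, bin_width: int = 50_000,
                      chrom: str = "chr") -> ContactMatrix:
    M = np.loadtxt(path)
    return ContactMatrix(counts=M, bin_width=bin_width, chrom=chrom)


def write_dense_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.counts, fmt="%.10g")


def read_sparse_triplets(path: str | Path, n_bins: int | None = None,
                         bin_width: int = 50_000, chrom: str = "chr") -> ContactMatrix:
    """Read (bin_i, bin_j, count) TSV; the matrix is symmetrised."""
    trip = np.loadtxt(path, ndmin=2)
    if trip.size == 0:
        raise ValueError("empty triplet file")
    i = trip[:, 0].astype(int)
    j = trip[:, 1].astype(int)
    c = trip[:, 2]
    n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
    M = np.zeros((n, n))
    M[i, j] = c
    low = np.tril_indices(n, -1)
    upper_t = M.T[low]
    fill = (M[low] == 0) & (upper_t != 0)
    M[low[0][fill], low[1][fill]] = upper_t[fill]
    M = np.triu(M) + np.triu(M, 1).T  # mirror to enforce symmetry
    return ContactMatrix(counts=M, bin_width=bin_width, chrom=chrom)


def write_sparse_triplets(matrix: ContactMatrix, path: str | Path) -> None:
    M = matrix.counts
    iu = np.triu_indices(M.shape[0])
    nz = M[iu] != 0
    with open(path, "w") as fh:
        for i, j, c in zip(iu[0][nz], iu[1][nz], M[iu][nz]):
            fh.write(f"{i}\t{j}\t{c:.10g}\n")
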