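"""Contact maps: construction from conformations, text I/O, KR balancing.

A contact map is a symmetric nonnegative matrix whose entry (i, j) counts
(or, after balancing, weights) contacts between loci i and j.  Unmappable
bins are kept in place but masked: they are removed before balancing and
re-inserted as zero rows, so genomic distances |i - j| always refer to the
original bin indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SYMMETRY_RTOL = 1e-8


class ConvergenceError(RuntimeError):
    """Matrix balancing failed to converge."""


@dataclass
class ContactMap:
    """Symmetric contact matrix with bin metadata and an unmappable mask."""

    matrix: np.ndarray
    bin_size: int = 1
    mask: Optional[np.ndarray] = None  # True = unmappable bin
    balanced: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n:
            raise ValueError("matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length must match matrix size")
        scale = max(1.0, float(np.max(self.matrix, initial=0.0)))
        dev = float(np.max(np.abs(self.matrix - self.matrix.T)))
        if dev > SYMMETRY_RTOL * scale:
            raise ValueError("matrix is not symmetric")
        if float(self.matrix.min(initial=0.0)) < 0:
            raise ValueError("matrix has negative entries")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def with_zero_rows_masked(self) -> "ContactMap":
        """Return a copy whose mask additionally covers all-zero rows."""
        zero = self.matrix.sum(axis=1) == 0
        extra = zero & ~self.mask
        if extra.any():
            log.info("masking %d all-zero bins", int(extra.sum()))
        return ContactMap(self.matrix.copy(), self.bin_size,
                          self.mask | zero, self.balanced)


# ---------------------------------------------------------------------------
# construction from polymer snapshots
# ---------------------------------------------------------------------------

def contacts_from_snapshots(snapshots: Sequence, threshold: float = 3.0,
                            ) -> ContactMap:
    """Count contacts over an ensemble of conformations.

    Entry (i, j), i != j, is the number of snapshots in which monomers i and
    j are closer than ``threshold`` (default: three lattice spacings); the
    diagonal is zero.
    """
    from . import _kernels

    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not snapshots:
        raise ValueError("need at least one snapshot")
    n = snapshots[0].n
    for s in snapshots:
        if s.n != n:
            raise ValueError("snapshots have differing chain lengths")
    arr = np.stack([np.asarray(s.coords, dtype=float) for s in snapshots])
    out = np.zeros((n, n), dtype=np.int32)
    _kernels.count_contacts(arr, float(threshold), out)
    return ContactMap(out.astype(float), bin_size=1)


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

def _kr_vector(a: np.ndarray, tol: float, delta: float = 0.1,
               big_delta: float = 3.0, max_outer: int = 300,
               max_mvp: int = 20000) -> np.ndarray:
    """Knight-Ruiz balancing vector for a symmetric nonnegative matrix.

    Inner-outer Newton iteration with conjugate-gradient inner solves;
    returns x such that diag(x) @ a @ diag(x) has unit row sums with
    residual 2-norm below ``tol``.
    """
    n = a.shape[0]
    e = np.ones(n)
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    x = e.copy()
    rt = tol * tol
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rho_km1
    rold = rout
    mvp = 0
    for _outer in range(max_outer):
        if rout <= rt:
            return x
        k = 0
        y = e.copy()
        innertol = max(eta * eta * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = rk @ z
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                raise ConvergenceError("KR inner iteration lost positivity")
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = np.min((big_delta - y[ind]) / ap[ind])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = rk @ z
            if mvp + k > max_mvp:
                raise ConvergenceError("KR exceeded matrix-vector budget")
        x = x * y
        v = x * (a @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o * eta_o > 0.1:
            eta = max(eta, g * eta_o * eta_o)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    raise ConvergenceError(
        f"KR did not converge in {max_outer} outer iterations "
        f"(residual {np.sqrt(rout):.3e}); matrix may be unbalanceable"
    )


def kr_balance(cmap: ContactMap, tol: float = 1e-7,
               drop_diagonal: bool = True) -> ContactMap:
    """Balance a contact map with the Knight-Ruiz algorithm.

    Masked bins (including rows that sum to zero) are removed before
    balancing and re-inserted as zero rows; every remaining row and column
    of the result sums to one within ``1e-6``.  Self-contacts are dropped
    first by default, since downstream community detection excludes them.
    """
    work = cmap.with_zero_rows_masked()
    m = work.matrix.copy()
    if drop_diagonal:
        np.fill_diagonal(m, 0.0)
        work = ContactMap(m, work.bin_size, work.mask, False)
        work = work.with_zero_rows_masked()
        m = work.matrix
    keep = work.unmasked()
    sub = m[np.ix_(keep, keep)]
    if sub.shape[0] == 0:
        raise ValueError("all bins are masked; nothing to balance")
    x = _kr_vector(sub, tol=tol)
    bal_sub = sub * np.outer(x, x)
    out = np.zeros_like(m)
    out[np.ix_(keep, keep)] = bal_sub
    return ContactMap(out, work.bin_size, work.mask, balanced=True)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_matrix(cmap: ContactMap, path, fmt: str = "dense") -> None:
    """Write a contact map as text.

    ``dense``: whitespace-separated full matrix.  ``coo``: tab-separated
    ``i j value`` triples for the upper triangle plus diagonal, 0-based.
    A ``#`` header records bin size, mask and balancing state.
    """
    header = (f"# bin_size={cmap.bin_size}\n"
              f"# balanced={int(cmap.balanced)}\n"
              f"# mask={','.join(map(str, np.where(cmap.mask)[0]))}\n")
    with open(path, "w") as fh:
        fh.write(header)
        if fmt == "dense":
            np.savetxt(fh, cmap.matrix, fmt="%.10g")
        elif fmt == "coo":
            iu, ju = np.nonzero(np.triu(cmap.matrix))
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{cmap.matrix[i, j]:.10g}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_matrix(path, fmt: str = "dense", bin_size: Optional[int] = None,
                n_bins: Optional[int] = None) -> ContactMap:
    """Read a contact map written as dense text or sparse coo triples.

    Sparse triples are interpreted as upper-triangle-plus-diagonal and
    symmetrized; an entry given on both sides must agree.  All-zero rows
    are masked on read.  Asymmetric dense input is an error.
    """
    meta = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            data_lines.append(stripped)
    if not data_lines:
        raise ValueError(f"{path}: no data lines")
    if fmt == "dense":
        try:
            mat = np.array([[float(tok) for tok in ln.split()]
                            for ln in data_lines])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed dense line: {exc}") from exc
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: dense matrix is not square")
        if not np.allclose(mat, mat.T, rtol=SYMMETRY_RTOL, atol=1e-12):
            raise ValueError(f"{path}: dense matrix is asymmetric")
    elif fmt == "coo":
        try:
            rows = [ln.split() for ln in data_lines]
            ijv = [(int(r[0]), int(r[1]), float(r[2])) for r in rows]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed triple: {exc}") from exc
        size = n_bins if n_bins is not None else max(
            max(i for i, _, _ in ijv), max(j for _, j, _ in ijv)) + 1
        mat = np.zeros((size, size))
        seen = {}
        for i, j, v in ijv:
            a, b = (i, j) if i <= j else (j, i)
            if (a, b) in seen and not np.isclose(seen[(a, b)], v):
                raise ValueError(
                    f"{path}: conflicting values for pair ({a}, {b})")
            seen[(a, b)] = v
            mat[a, b] = v
            mat[b, a] = v
    else:
        raise ValueError(f"unknown format {fmt!r}")
    bs = bin_size if bin_size is not None else int(meta.get("bin_size", 1))
    mask = np.zeros(mat.shape[0], dtype=bool)
    mask_spec = meta.get("mask", "")
    if mask_spec:
        mask[[int(t) for t in mask_spec.split(",")]] = True
    cmap = ContactMap(mat, bs, mask, balanced=bool(int(meta.get("balanced", 0))))
    return cmap.with_zero_rows_masked()


def read_bed_mask(path, bin_size: int, n_bins: int) -> np.ndarray:
    """Boolean mask of bins covered by intervals in a 0-based half-open BED
    file (chromosome column ignored: single-chromosome maps)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    mask = np.zeros(n_bins, dtype=bool)
    for start, end in zip(bed["start"], bed["end"]):
        lo = int(start) // bin_size
        hi = -(-int(end) // bin_size)
        mask[max(lo, 0):min(hi, n_bins)] = True
    return mask
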