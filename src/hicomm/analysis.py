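"""Polymer-physics and genomics post-processing of partitions.

Covers contiguous-segment decomposition of (generally non-contiguous) 3D
communities, end-to-end scaling curves R(s), radius of gyration and
gyration-tensor asphericity, boundary overlap against reference positions
(e.g. published TAD borders or CTCF sites), and per-community summaries of
a genomic signal track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .community import MASKED_LABEL, Partition
from .polymer import Conformation


# ---------------------------------------------------------------------------
# segment decomposition
# ---------------------------------------------------------------------------

@dataclass
class SegmentDecomposition:
    """Maximal runs of equal community label along the chain.

    ``segments`` is an ordered list of (start_bin, end_bin, community_id)
    with inclusive ends; masked bins separate runs and belong to none.
    """

    segments: List[Tuple[int, int, int]]
    n_segments_per_community: Dict[int, int]

    @property
    def non_contiguous_communities(self) -> List[int]:
        return sorted(c for c, n in self.n_segments_per_community.items()
                      if n >= 2)


def decompose_segments(part: Partition) -> SegmentDecomposition:
    """Split a partition into maximal contiguous same-label segments."""
    labels = np.asarray(part.labels)
    segments: List[Tuple[int, int, int]] = []
    start = None
    prev = None
    for i, lab in enumerate(labels):
        if lab == MASKED_LABEL:
            if start is not None:
                segments.append((start, i - 1, int(prev)))
                start = None
            prev = None
            continue
        if prev is None or lab != prev:
            if start is not None:
                segments.append((start, i - 1, int(prev)))
            start = i
        prev = lab
    if start is not None:
        segments.append((start, len(labels) - 1, int(prev)))
    counts: Dict[int, int] = {}
    for _, _, c in segments:
        counts[c] = counts.get(c, 0) + 1
    return SegmentDecomposition(segments, counts)


def segments_to_labels(dec: SegmentDecomposition, n: int) -> np.ndarray:
    """Inverse of :func:`decompose_segments` (masked bins become -1)."""
    labels = np.full(n, MASKED_LABEL, dtype=np.int64)
    for start, end, c in dec.segments:
        labels[start:end + 1] = c
    return labels


# ---------------------------------------------------------------------------
# end-to-end scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingCurve:
    """Mean end-to-end distance versus contour separation.

    ``sem`` is the standard error of the mean across the ensemble (or
    across segments, for community curves); ``fitted_exponent`` is the
    log-log least-squares slope over the fit window used.
    """

    s: np.ndarray
    mean_R: np.ndarray
    sem: np.ndarray
    fitted_exponent: float
    fit_window: Tuple[float, float]
    n_obs: Optional[np.ndarray] = None


def default_fit_window(n: int) -> Tuple[float, float]:
    """Intermediate contour separations: [8, N**(2/3)].

    Short separations are dominated by lattice discreteness, long ones by
    finite chain size, so fits use the window in between.
    """
    return 8.0, float(n) ** (2.0 / 3.0)


def fit_loglog_slope(s: np.ndarray, y: np.ndarray,
                     window: Tuple[float, float]) -> float:
    """Least-squares slope of log y versus log s restricted to a window."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = (s >= window[0]) & (s <= window[1]) & (y > 0)
    if sel.sum() < 2:
        return math.nan
    slope, _ = np.polyfit(np.log(s[sel]), np.log(y[sel]), 1)
    return float(slope)


def log_spaced_s(n: int, per_decade: int = 12) -> np.ndarray:
    """Integer contour separations spaced evenly in log between 1 and n-1."""
    grid = np.unique(np.round(np.logspace(
        0, np.log10(n - 1), int(per_decade * np.log10(n - 1)) + 1
    )).astype(int))
    return grid[(grid >= 1) & (grid <= n - 1)]


def end_to_end_curve(
    confs: Sequence[Conformation],
    subchains: str = "all",
    partitions: Optional[Sequence[Partition]] = None,
    s_values: Optional[np.ndarray] = None,
    fit_window: Optional[Tuple[float, float]] = None,
) -> ScalingCurve:
    """Ensemble end-to-end distance R(s).

    ``subchains="all"``: R(s) averages ||r_{i+s} - r_i|| over all start
    positions and all conformations, on a log-spaced grid of s.

    ``subchains="community_segments"``: one observation per contiguous
    community segment, at s = (segment length in bonds), using the two
    boundary monomers; observations are pooled across the ensemble and
    binned onto the same log grid.  ``partitions`` must align with
    ``confs`` by monomer index.
    """
    if not confs:
        raise ValueError("need at least one conformation")
    n = confs[0].n
    if s_values is None:
        s_values = log_spaced_s(n)
    window = fit_window if fit_window is not None else default_fit_window(n)

    if subchains == "all":
        per_chain = np.empty((len(confs), len(s_values)))
        for ci, conf in enumerate(confs):
            xyz = conf.coords
            for si, s in enumerate(s_values):
                d = xyz[s:] - xyz[:-s]
                per_chain[ci, si] = np.mean(np.linalg.norm(d, axis=1))
        mean_r = per_chain.mean(axis=0)
        sem = (per_chain.std(axis=0, ddof=1) / math.sqrt(len(confs))
               if len(confs) > 1 else np.zeros_like(mean_r))
        nobs = np.full(len(s_values), len(confs))
    elif subchains == "community_segments":
        if partitions is None or len(partitions) != len(confs):
            raise ValueError("community_segments requires aligned partitions")
        obs_s: List[float] = []
        obs_r: List[float] = []
        for conf, part in zip(confs, partitions):
            dec = decompose_segments(part)
            for start, end, _c in dec.segments:
                if end <= start:
                    continue
                r = float(np.linalg.norm(conf.coords[end] - conf.coords[start]))
                obs_s.append(float(end - start))
                obs_r.append(r)
        if not obs_s:
            raise ValueError("no segments of length >= 2 found")
        obs_s_arr = np.array(obs_s)
        obs_r_arr = np.array(obs_r)
        # bin observations onto the log grid (nearest grid point in log s)
        edges = np.sqrt(s_values[:-1] * s_values[1:])
        idx = np.searchsorted(edges, obs_s_arr)
        mean_r = np.full(len(s_values), np.nan)
        sem = np.full(len(s_values), np.nan)
        nobs = np.zeros(len(s_values), dtype=int)
        for b in range(len(s_values)):
            vals = obs_r_arr[idx == b]
            nobs[b] = len(vals)
            if len(vals):
                mean_r[b] = vals.mean()
                sem[b] = (vals.std(ddof=1) / math.sqrt(len(vals))
                          if len(vals) > 1 else 0.0)
        keep = nobs > 0
        s_values, mean_r, sem, nobs = (s_values[keep], mean_r[keep],
                                       sem[keep], nobs[keep])
    else:
        raise ValueError(f"unknown subchains mode {subchains!r}")

    exponent = fit_loglog_slope(s_values, mean_r, window)
    return ScalingCurve(np.asarray(s_values, dtype=float), mean_r, sem,
                        exponent, window, nobs)


def compare_curves(segment_curve: ScalingCurve, all_curve: ScalingCurve,
                   min_obs: int = 5,
                   s_range: Optional[Tuple[float, float]] = None,
                   ) -> Tuple[float, int]:
    """Fraction of matched s bins where the segment curve lies below the
    all-subchain curve.

    Only bins with at least ``min_obs`` segment observations (and present
    in both curves) are compared.  Returns (fraction_below, n_bins).
    """
    frac_below = 0
    total = 0
    all_lookup = {float(s): r for s, r in zip(all_curve.s, all_curve.mean_R)}
    for s, r, n in zip(segment_curve.s, segment_curve.mean_R,
                       segment_curve.n_obs):
        if n < min_obs or float(s) not in all_lookup:
            continue
        if s_range is not None and not s_range[0] <= s <= s_range[1]:
            continue
        total += 1
        if r < all_lookup[float(s)]:
            frac_below += 1
    if total == 0:
        return math.nan, 0
    return frac_below / total, total


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------

def radius_of_gyration(conf_or_coords) -> float:
    """Radius of gyration sqrt(mean squared distance from the centroid).

    Equals the pair-distance form sqrt((1 / 2N^2) sum_{i,j} ||r_i - r_j||^2).
    """
    coords = getattr(conf_or_coords, "coords", conf_or_coords)
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def normalize_by_rg(curve: ScalingCurve, rg: float) -> ScalingCurve:
    """Scale a curve's vertical axis by 2 * R_g (the average chain size)."""
    scale = 2.0 * rg
    return ScalingCurve(curve.s, curve.mean_R / scale, curve.sem / scale,
                        curve.fitted_exponent, curve.fit_window, curve.n_obs)


def asphericity(conf_or_coords) -> float:
    """Gyration-tensor asphericity b = (l1 - (l2 + l3)/2) / (l1 + l2 + l3).

    0 for spherically symmetric point sets, 1 for collinear ones.
    """
    coords = getattr(conf_or_coords, "coords", conf_or_coords)
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / coords.shape[0]
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    tr = lam.sum()
    if tr <= 0:
        return 0.0
    return float((lam[0] - 0.5 * (lam[1] + lam[2])) / tr)


# ---------------------------------------------------------------------------
# border overlap and community summaries
# ---------------------------------------------------------------------------

def predicted_borders(part: Partition) -> np.ndarray:
    """Community borders: first bin of each new segment.

    The chain start and bins adjacent to masked regions are not borders
    (they would trivially inflate any overlap measure).
    """
    dec = decompose_segments(part)
    labels = np.asarray(part.labels)
    borders = []
    for start, _end, _c in dec.segments:
        if start == 0:
            continue
        if labels[start - 1] == MASKED_LABEL:
            continue
        borders.append(start)
    return np.array(sorted(borders), dtype=int)


def border_overlap(part: Partition, reference: Sequence[int],
                   window: int = 1) -> Tuple[float, float]:
    """Overlap between predicted community borders and reference positions.

    Returns (fraction of predicted borders with a reference position within
    +/- ``window`` bins, the reciprocal fraction).  An empty reference (or
    an empty prediction) contributes 0.0 on that side.
    """
    pred = predicted_borders(part)
    ref = np.asarray(sorted(set(int(r) for r in reference)), dtype=int)

    def frac(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) == 0 or len(b) == 0:
            return 0.0
        pos = np.searchsorted(b, a)
        near = np.zeros(len(a), dtype=bool)
        for off in (-1, 0):
            idx = np.clip(pos + off, 0, len(b) - 1)
            near |= np.abs(b[idx] - a) <= window
        return float(near.mean())

    return frac(pred, ref), frac(ref, pred)


def tads_per_community(part: Partition) -> Dict[str, float]:
    """Community count and mean contiguous segments (TAD-like blocks) per
    community, at this partition's resolution."""
    dec = decompose_segments(part)
    n_comm = len(dec.n_segments_per_community)
    if n_comm == 0:
        return {"gamma": part.gamma, "n_communities": 0,
                "mean_segments_per_community": math.nan}
    mean_seg = len(dec.segments) / n_comm
    return {"gamma": part.gamma, "n_communities": n_comm,
            "mean_segments_per_community": mean_seg}


def signal_by_community(part: Partition, track: np.ndarray,
                        min_size: int = 50) -> pd.DataFrame:
    """Median and quartiles of a per-bin signal within each community.

    Communities smaller than ``min_size`` bins are omitted.  Masked bins
    and NaN track values are ignored.
    """
    labels = np.asarray(part.labels)
    track = np.asarray(track, dtype=float)
    if track.shape[0] != labels.shape[0]:
        raise ValueError("track length must match partition length")
    df = pd.DataFrame({"community": labels, "value": track})
    df = df[(df["community"] != MASKED_LABEL) & np.isfinite(df["value"])]
    rows = []
    for comm, grp in df.groupby("community"):
        if len(grp) < min_size:
            continue
        q1, med, q3 = np.percentile(grp["value"], [25, 50, 75])
        rows.append({"community": int(comm), "size": int(len(grp)),
                     "q1": q1, "median": med, "q3": q3})
    out = pd.DataFrame(rows,
                       columns=["community", "size", "q1", "median", "q3"])
    return out.sort_values("size", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genomic interval helpers
# ---------------------------------------------------------------------------

def bed_to_bins(path, bin_size: int, use: str = "start") -> np.ndarray:
    """Convert BED intervals (0-based half-open) to sorted unique bin
    indices using the interval start or midpoint."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if use == "start":
        pos = bed["start"].to_numpy()
    elif use == "midpoint":
        pos = ((bed["start"] + bed["end"]) // 2).to_numpy()
    else:
        raise ValueError(f"unknown anchor {use!r}")
    return np.unique(pos // bin_size).astype(int)


def bedgraph_to_track(path, bin_size: int, n_bins: int) -> np.ndarray:
    """Coverage-weighted mean bedGraph signal per bin (NaN where no data)."""
    bg = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "value"])
    total = np.zeros(n_bins)
    weight = np.zeros(n_bins)
    for start, end, value in zip(bg["start"], bg["end"], bg["value"]):
        start, end = int(start), int(end)
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            total[b] += value * (hi - lo)
            weight[b] += hi - lo
    with np.errstate(invalid="ignore"):
        out = total / weight
    return out
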