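"""End-to-end workflows: simulate -> contacts -> balance -> detect -> analyze.

These are the desk-scale stand-ins for a Hi-C analysis: fractal-globule and
equilibrium-globule ensembles with their aggregated contact maps, the
ensemble contact-probability curve P(s) and its decay exponent, and a
fixture bundle that regenerates every test input from a single seed without
any external data.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import analysis as ana
from . import community as comm
from . import contacts as cm
from . import polymer as poly

log = logging.getLogger(__name__)

CONTACT_THRESHOLD = 3.0  # lattice spacings


def _chain_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def simulate_fg_map(
    n_monomers: int,
    seed: int,
    n_snapshots: int = 100,
    threshold: float = CONTACT_THRESHOLD,
    a_bias: float = 1e4,
    epsilon: float = 1e-4,
) -> Tuple[poly.Conformation, cm.ContactMap]:
    """One fractal globule and its snapshot-aggregated contact map."""
    conf = poly.generate_cdp(poly.CdpParams(N=n_monomers, A=a_bias,
                                            epsilon=epsilon, seed=seed))
    snaps = poly.anneal_snapshots(
        conf, poly.AnnealParams(n_snapshots=n_snapshots, seed=seed + 1))
    cmap = cm.contacts_from_snapshots(snaps, threshold=threshold)
    return conf, cmap


def simulate_eg_map(
    n_monomers: int,
    seed: int,
    n_snapshots: int = 100,
    threshold: float = CONTACT_THRESHOLD,
    radius: Optional[float] = None,
) -> Tuple[poly.Conformation, cm.ContactMap]:
    """One equilibrium globule and its snapshot-aggregated contact map."""
    conf = poly.generate_equilibrium_globule(n_monomers, radius=radius,
                                             seed=seed)
    snaps = poly.anneal_snapshots(
        conf, poly.AnnealParams(n_snapshots=n_snapshots, seed=seed + 1))
    cmap = cm.contacts_from_snapshots(snaps, threshold=threshold)
    return conf, cmap


# ---------------------------------------------------------------------------
# contact probability
# ---------------------------------------------------------------------------

def contact_probability(cmap: cm.ContactMap, n_snapshots: int) -> pd.DataFrame:
    """Mean contact probability per contour separation s.

    P(s) is the average of entries on the s-th diagonal divided by the
    number of snapshots registered.
    """
    n = cmap.n_bins
    s = np.arange(1, n)
    p = np.array([cmap.matrix.diagonal(k).mean() for k in s]) / n_snapshots
    return pd.DataFrame({"s": s, "P": p})


def mean_contact_probability(curves: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average P(s) curves over an ensemble (equal s grids required)."""
    s = curves[0]["s"].to_numpy()
    p = np.mean([c["P"].to_numpy() for c in curves], axis=0)
    return pd.DataFrame({"s": s, "P": p})


def contact_decay_exponent(ps: pd.DataFrame,
                           window: Tuple[float, float] = (8.0, 512.0),
                           per_decade: int = 8) -> float:
    """Log-log slope of P(s) over a window, fitted on log-binned means.

    Binning in log s gives every scale equal weight in the fit, which is
    the standard way to read off a power-law exponent from P(s).
    """
    s = ps["s"].to_numpy(dtype=float)
    p = ps["P"].to_numpy(dtype=float)
    sel = (s >= window[0]) & (s <= window[1]) & (p > 0)
    s, p = s[sel], p[sel]
    if len(s) < 2:
        return math.nan
    n_bins = max(2, int(per_decade * math.log10(window[1] / window[0])))
    edges = np.logspace(math.log10(window[0]), math.log10(window[1]),
                        n_bins + 1)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            xs.append(np.log(s[m]).mean())
            ys.append(math.log(p[m].mean()))
    if len(xs) < 2:
        return math.nan
    slope, _ = np.polyfit(xs, ys, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def fg_ensemble_stats(
    n_monomers: int = 4096,
    n_chains: int = 20,
    n_snapshots: int = 100,
    seed: int = 0,
    threshold: float = CONTACT_THRESHOLD,
    gamma: Optional[float] = None,
    null: Optional[comm.NullModelSpec] = None,
    n_restarts: int = 3,
    keep_maps: bool = False,
    n_partition_chains: Optional[int] = None,
) -> Dict:
    """Generate a fractal-globule ensemble and its summary statistics.

    Per chain: conformation, aggregated contact map, P(s).  If ``gamma``
    is given, the KR-balanced map is partitioned with the FG-null Louvain
    and the partition is kept (for community-compactness analyses);
    ``n_partition_chains`` limits detection to the first chains only.
    Contact maps are discarded after use unless ``keep_maps``.
    """
    out: Dict = {"confs": [], "ps": [], "partitions": [], "maps": []}
    for i, s in enumerate(_chain_seeds(seed, n_chains)):
        conf, cmap = simulate_fg_map(n_monomers, s, n_snapshots, threshold)
        out["confs"].append(conf)
        out["ps"].append(contact_probability(cmap, n_snapshots))
        if gamma is not None and (n_partition_chains is None
                                  or i < n_partition_chains):
            spec = null or comm.NullModelSpec("FG", 1.0)
            balanced = cm.kr_balance(cmap)
            part = comm.louvain(balanced, spec, gamma, seed=s,
                                n_restarts=n_restarts)
            out["partitions"].append(part)
        if keep_maps:
            out["maps"].append(cmap)
        log.info("FG chain %d/%d done", i + 1, n_chains)
    out["ps_mean"] = mean_contact_probability(out["ps"])
    return out


def eg_ensemble_stats(
    n_monomers: int = 4096,
    n_chains: int = 20,
    n_snapshots: int = 100,
    seed: int = 0,
    threshold: float = CONTACT_THRESHOLD,
    gamma: Optional[float] = None,
    null: Optional[comm.NullModelSpec] = None,
    n_restarts: int = 3,
    radius: Optional[float] = None,
    n_partition_chains: Optional[int] = None,
) -> Dict:
    """Equilibrium-globule counterpart of :func:`fg_ensemble_stats`."""
    out: Dict = {"confs": [], "ps": [], "partitions": []}
    for i, s in enumerate(_chain_seeds(seed + 101, n_chains)):
        conf, cmap = simulate_eg_map(n_monomers, s, n_snapshots, threshold,
                                     radius=radius)
        out["confs"].append(conf)
        out["ps"].append(contact_probability(cmap, n_snapshots))
        if gamma is not None and (n_partition_chains is None
                                  or i < n_partition_chains):
            spec = null or comm.NullModelSpec("FG", 1.0)
            balanced = cm.kr_balance(cmap)
            part = comm.louvain(balanced, spec, gamma, seed=s,
                                n_restarts=n_restarts)
            out["partitions"].append(part)
        log.info("EG chain %d/%d done", i + 1, n_chains)
    out["ps_mean"] = mean_contact_probability(out["ps"])
    return out


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def pipeline_fixture(
    outdir,
    n_monomers: int = 512,
    n_chains: int = 5,
    gammas: Sequence[float] = (0.4, 0.6, 0.8),
    seed: int = 0,
    n_snapshots: int = 50,
) -> Dict:
    """Run the full simulate -> contacts -> balance -> detect -> analyze
    pipeline into a directory, as a desk-scale stand-in for Hi-C data.

    Writes conformations (xyz text), contact maps (dense text), partitions
    (TSV) and summary tables; deterministic per seed.  Returns the file
    inventory and in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = comm.NullModelSpec("FG", 1.0)
    inventory = []
    results: Dict = {"partitions": {}, "scan_tables": []}

    confs = []
    balanced_maps = []
    for i, s in enumerate(_chain_seeds(seed, n_chains)):
        conf, cmap = simulate_fg_map(n_monomers, s, n_snapshots)
        confs.append(conf)
        poly.write_xyz(conf, outdir / f"fg_{i}.xyz")
        cm.write_matrix(cmap, outdir / f"fg_{i}.counts.txt", fmt="dense")
        bal = cm.kr_balance(cmap)
        cm.write_matrix(bal, outdir / f"fg_{i}.balanced.txt", fmt="dense")
        balanced_maps.append(bal)
        inventory += [f"fg_{i}.xyz", f"fg_{i}.counts.txt",
                      f"fg_{i}.balanced.txt"]

    for i, bal in enumerate(balanced_maps):
        parts, table = comm.gamma_scan(bal, spec, gammas, seed=seed + i,
                                       n_restarts=3)
        results["scan_tables"].append(table)
        for part in parts:
            key = (i, part.gamma)
            results["partitions"][key] = part
            tsv = outdir / f"fg_{i}.gamma{part.gamma:g}.communities.tsv"
            write_partition(part, tsv, bin_size=1)
            inventory.append(tsv.name)

    curve_all = ana.end_to_end_curve(confs, "all")
    pd.DataFrame({"s": curve_all.s, "mean_R": curve_all.mean_R,
                  "sem": curve_all.sem}).to_csv(
        outdir / "fg_end_to_end.tsv", sep="\t", index=False)
    inventory.append("fg_end_to_end.tsv")

    meta = {"n_monomers": n_monomers, "n_chains": n_chains,
            "gammas": list(map(float, gammas)), "seed": seed,
            "n_snapshots": n_snapshots,
            "contact_threshold": CONTACT_THRESHOLD,
            "null": {"kind": spec.kind, "alpha": spec.alpha}}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    inventory.append("run_metadata.json")
    results["inventory"] = inventory
    results["confs"] = confs
    results["curve_all"] = curve_all
    return results


def write_partition(part: comm.Partition, path, bin_size: int = 1) -> None:
    """TSV with bin index, genomic start coordinate and community id, plus a
    sidecar JSON metadata record (Q, gamma, seed, null model)."""
    n = len(part.labels)
    df = pd.DataFrame({
        "bin_index": np.arange(n),
        "chrom_coord_start": np.arange(n) * bin_size,
        "community_id": part.labels,
    })
    df.to_csv(path, sep="\t", index=False)
    meta = {"gamma": part.gamma, "Q": None if math.isnan(part.Q) else part.Q,
            "seed": part.seed,
            "null": None if part.null is None else
            {"kind": part.null.kind, "alpha": part.null.alpha}}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_partition(path) -> comm.Partition:
    """Read a partition TSV written by :func:`write_partition`."""
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(str(path) + ".json")
    gamma, q, seed = math.nan, math.nan, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        gamma = meta.get("gamma", math.nan)
        q = meta.get("Q")
        q = math.nan if q is None else q
        seed = meta.get("seed")
    return comm.Partition(df["community_id"].to_numpy(), gamma=gamma,
                          Q=q, seed=seed)
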