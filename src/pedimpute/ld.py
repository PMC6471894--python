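"""Linkage disequilibrium: Lewontin's D′ on phased panels and its
distance-window and MAF-product summaries.

D′ normalises the haplotype-frequency covariance D = f11 − p·q by its
frequency-constrained maximum; |D′| is reported, in [0, 1]. Profiles bin
within-chromosome pairs by physical distance (500-kb windows by default) and
average D′ weighted by the product of the two minor allele frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import HaplotypeSet


def dprime(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """|D′| between two phased biallelic haplotype columns.

    NA when either column is monomorphic; D = 0 maps to 0.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("haplotype columns must have equal length >= 2")
    p1 = a.mean()
    q1 = b.mean()
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        return float("nan")
    f11 = (a * b).mean()
    d = f11 - p1 * q1
    if d == 0:
        return 0.0
    if d > 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    else:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    return float(abs(d) / dmax)


def _pairwise_dprime_block(hap_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs |D′| and per-site MAF for a haplotypes x sites 0/1 block."""
    h = hap_cols.astype(np.float64)
    n, m = h.shape
    p = h.mean(axis=0)
    f11 = (h.T @ h) / n
    d = f11 - np.outer(p, p)
    pos_max = np.minimum(np.outer(p, 1 - p), np.outer(1 - p, p))
    neg_max = np.minimum(np.outer(p, p), np.outer(1 - p, 1 - p))
    dmax = np.where(d > 0, pos_max, neg_max)
    with np.errstate(invalid="ignore", divide="ignore"):
        dp = np.where(d == 0, 0.0, np.abs(d) / dmax)
    mono = (p == 0) | (p == 1)
    dp[mono, :] = np.nan
    dp[:, mono] = np.nan
    maf = np.minimum(p, 1 - p)
    return dp, maf


def pairwise_ld(
    hs: HaplotypeSet,
    max_distance_bp: int,
    site_filter: pd.DataFrame | None = None,
    max_sites_per_chrom: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-chromosome LD pairs with distance <= ``max_distance_bp``.

    ``site_filter`` restricts the panel to listed (chrom, pos) — typically
    the high-imputation-quality selection. ``max_sites_per_chrom`` takes a
    seeded random subsample before pairing, for desk-scale profiling of
    dense panels. Pairs with undefined D′ (monomorphic member) are dropped.
    """
    sites = hs.sites
    keep = np.arange(len(sites))
    if site_filter is not None:
        keys = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
        want = pd.MultiIndex.from_frame(site_filter[["chrom", "pos"]])
        keep = keys.get_indexer(want)
        keep = np.sort(keep[keep >= 0])
    rng = np.random.default_rng(seed)
    frames = []
    chroms = sites["chrom"].to_numpy()
    hap2d = hs.hap.reshape(2 * hs.n_samples, hs.n_sites)
    for chrom in pd.unique(chroms[keep]):
        idx = keep[chroms[keep] == chrom]
        if max_sites_per_chrom is not None and idx.size > max_sites_per_chrom:
            idx = np.sort(rng.choice(idx, size=max_sites_per_chrom, replace=False))
        if idx.size < 2:
            continue
        pos = sites["pos"].to_numpy()[idx]
        dp, maf = _pairwise_dprime_block(hap2d[:, idx])
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[jj] - pos[ii]
        ok = (dist > 0) & (dist <= max_distance_bp)
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        vals = dp[ii, jj]
        good = ~np.isnan(vals)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_a": pos[ii[good]],
                    "pos_b": pos[jj[good]],
                    "distance_bp": dist[good],
                    "dprime": vals[good],
                    "maf_a": maf[ii[good]],
                    "maf_b": maf[jj[good]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos_a", "pos_b", "distance_bp", "dprime",
                     "maf_a", "maf_b", "maf_product"]
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs["maf_product"] = pairs["maf_a"] * pairs["maf_b"]
    return pairs


def weighted_mean_dprime(
    pairs: pd.DataFrame,
    window_bp: int = 500_000,
    weighting: str = "maf_product",
) -> pd.DataFrame:
    """Mean D′ per consecutive distance window, weighted by the MAF product
    (or unweighted with ``weighting="uniform"``); empty windows are NA."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if weighting not in ("maf_product", "uniform"):
        raise ValueError("weighting must be 'maf_product' or 'uniform'")
    if pairs.empty:
        return pd.DataFrame(columns=["window", "distance_lo", "distance_hi",
                                     "mean_dprime", "n_pairs"])
    win = ((pairs["distance_bp"].astype(np.int64) - 1) // window_bp).to_numpy()
    w = (
        pairs["maf_product"].to_numpy()
        if weighting == "maf_product"
        else np.ones(len(pairs))
    )
    dp = pairs["dprime"].to_numpy()
    out = []
    for k in range(int(win.max()) + 1):
        mask = win == k
        wk = w[mask]
        out.append(
            {
                "window": k,
                "distance_lo": k * window_bp + 1,
                "distance_hi": (k + 1) * window_bp,
                "mean_dprime": (
                    float(np.average(dp[mask], weights=wk))
                    if mask.any() and wk.sum() > 0
                    else float("nan")
                ),
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(out)


def maf_product_profile(
    pairs: pd.DataFrame,
    distance_bins: np.ndarray | None = None,
    mafprod_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted-mean D′ on a (distance bin x MAF-product bin) grid.

    Returns a long-format frame with bin edges, weighted mean D′ and pair
    counts; counts over the grid sum to the number of input pairs.
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=["distance_bin", "mafprod_bin", "mean_dprime", "n_pairs"]
        )
    if distance_bins is None:
        distance_bins = np.linspace(0, pairs["distance_bp"].max(), 11)
    if mafprod_bins is None:
        mafprod_bins = np.linspace(0, 0.25, 11)
    d_idx = np.clip(
        np.digitize(pairs["distance_bp"], distance_bins) - 1, 0,
        len(distance_bins) - 2,
    )
    m_idx = np.clip(
        np.digitize(pairs["maf_product"], mafprod_bins) - 1, 0,
        len(mafprod_bins) - 2,
    )
    dp = pairs["dprime"].to_numpy()
    w = pairs["maf_product"].to_numpy()
    rows = []
    for di in np.unique(d_idx):
        for mi in np.unique(m_idx[d_idx == di]):
            mask = (d_idx == di) & (m_idx == mi)
            wk = w[mask]
            mean = (
                float(np.average(dp[mask], weights=wk)) if wk.sum() > 0
                else float(dp[mask].mean())
            )
            rows.append(
                {
                    "distance_bin": int(di),
                    "mafprod_bin": int(mi),
                    "mean_dprime": mean,
                    "n_pairs": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)
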