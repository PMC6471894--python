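"""Per-SNP and per-individual explanatory factors for imputation quality.

Per SNP: the minor allele frequency in the sequenced panel (FreqOri), the
Wigginton exact Hardy-Weinberg test p-value (hweOri), summed site depth
(DEPTH), calling quality (QUAL) and the chip-to-sequence marker density
ratio in non-overlapping 500-kb windows (RatioDensity); per individual the
mean sequencing coverage (MEAN_DEPTH). The assembled table is the hand-off
to any external factor-importance analysis; a Spearman ranking is provided
for in-repo checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import MISSING, GenotypeMatrix


def minor_allele_freq(dosages: np.ndarray) -> float:
    """Minor allele frequency from a dosage column; NA if all missing."""
    dosages = np.asarray(dosages)
    called = dosages != MISSING
    n = int(called.sum())
    if n == 0:
        return float("nan")
    p = dosages[called].sum() / (2.0 * n)
    return float(min(p, 1.0 - p))


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value (Wigginton et al. style).

    Conditional on the observed allele counts, heterozygote counts are
    enumerated through the standard recurrence; the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    Monomorphic samples return 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    h_obs = n_ab
    h_min = n_rare % 2
    h_max = min(n_rare, 2 * n - n_rare)
    probs = {}
    # start mid-range and apply the recurrence in both directions
    h_mid = h_min + 2 * ((n_rare * (2 * n - n_rare) // (2 * n) - h_min) // 2)
    h_mid = min(max(h_mid, h_min), h_max)
    probs[h_mid] = 1.0
    # upward: P(h+2)/P(h) = 4*rare_hom(h)*common_hom(h) / ((h+2)*(h+1))
    h = h_mid
    while h + 2 <= h_max:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[h + 2] = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
        h += 2
    h = h_mid
    while h - 2 >= h_min:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[h - 2] = probs[h] * h * (h - 1.0) / (
            4.0 * (rare_hom + 1.0) * (common_hom + 1.0)
        )
        h -= 2
    total = sum(probs.values())
    p_obs = probs[h_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return float(min(p, 1.0))


def hwe_exact_by_site(gm: GenotypeMatrix) -> np.ndarray:
    """hweOri per site from a genotype matrix (missing genotypes skipped)."""
    out = np.ones(gm.n_sites)
    dos = gm.dosage
    for j in range(gm.n_sites):
        col = dos[:, j]
        called = col != MISSING
        if not called.any():
            out[j] = np.nan
            continue
        c = col[called]
        out[j] = hwe_exact_pvalue(
            int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
        )
    return out


def density_ratio(
    chip_sites: pd.DataFrame,
    seq_sites: pd.DataFrame,
    window_bp: int = 500_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Chip/sequence marker-count ratio in non-overlapping windows.

    Windows are [k*window_bp + 1, (k+1)*window_bp] per chromosome (anchored
    at coordinate 1). Returns the per-window table and each sequence SNP's
    inherited ratio (aligned with ``seq_sites`` rows).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    def win(df: pd.DataFrame) -> pd.Series:
        return (df["pos"].astype(np.int64) - 1) // window_bp

    seq_w = win(seq_sites)
    chip_w = win(chip_sites)
    seq_counts = (
        pd.DataFrame({"chrom": seq_sites["chrom"], "window": seq_w})
        .groupby(["chrom", "window"]).size().rename("n_seq")
    )
    chip_counts = (
        pd.DataFrame({"chrom": chip_sites["chrom"], "window": chip_w})
        .groupby(["chrom", "window"]).size().rename("n_chip")
    )
    table = pd.concat([seq_counts, chip_counts], axis=1).fillna(0)
    table = table[table["n_seq"] > 0]
    table["ratio"] = table["n_chip"] / table["n_seq"]
    key = pd.MultiIndex.from_arrays([seq_sites["chrom"], seq_w])
    per_snp = table["ratio"].reindex(key).to_numpy()
    return table.reset_index(), per_snp


def mean_depth_by_individual(gm: GenotypeMatrix) -> pd.Series:
    """MEAN_DEPTH: arithmetic mean of per-site depth per sample."""
    if gm.depth is None:
        if gm.sample_depth is not None:
            return pd.Series(gm.sample_depth, index=gm.samples, name="MEAN_DEPTH")
        return pd.Series(np.nan, index=gm.samples, name="MEAN_DEPTH")
    return pd.Series(gm.depth.mean(axis=1), index=gm.samples, name="MEAN_DEPTH")


def snp_factors(
    seq: GenotypeMatrix,
    chip_sites: pd.DataFrame,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Per-SNP factor table: FreqOri, hweOri, DEPTH, QUAL, RatioDensity."""
    dos = seq.dosage
    called = dos != MISSING
    n_called = np.maximum(called.sum(axis=0), 1)
    p = (dos * called).sum(axis=0) / (2.0 * n_called)
    freq_ori = np.minimum(p, 1.0 - p)
    hwe = hwe_exact_by_site(seq)
    _, ratio = density_ratio(chip_sites, seq.sites, window_bp=window_bp)
    return pd.DataFrame(
        {
            "chrom": seq.sites["chrom"].to_numpy(),
            "pos": seq.sites["pos"].to_numpy(),
            "FreqOri": freq_ori,
            "hweOri": hwe,
            "DEPTH": seq.sites["site_depth"].to_numpy(dtype=float),
            "QUAL": seq.sites["qual"].to_numpy(dtype=float),
            "RatioDensity": ratio,
        }
    )


def assemble_factor_table(
    quality: pd.DataFrame,
    factors: pd.DataFrame,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inner-join per-SNP quality metrics with factors on (chrom, pos);
    optionally merge an externally computed per-SNP LD weight column."""
    for df, name in ((quality, "quality"), (factors, "factors")):
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError(f"duplicated (chrom,pos) in {name} table")
    table = quality.merge(factors, on=["chrom", "pos"], how="inner")
    if table.empty:
        import logging

        logging.getLogger(__name__).warning(
            "assemble_factor_table: no overlapping sites between quality and factors"
        )
    if weights is not None:
        w = weights.rename(columns={weights.columns[-1]: "Weight"})
        table = table.merge(w[["chrom", "pos", "Weight"]], on=["chrom", "pos"],
                            how="left")
    return table


def rank_factor_correlations(
    table: pd.DataFrame,
    target: str = "Props",
    factor_cols: tuple[str, ...] = ("RatioDensity", "DEPTH", "QUAL", "FreqOri", "hweOri"),
) -> pd.DataFrame:
    """Spearman correlation of each factor with a quality metric, ranked by
    absolute value — the in-repo qualitative stand-in for external
    factor-importance analyses."""
    rows = []
    for col in factor_cols:
        sub = table[[target, col]].dropna()
        rho = spearmanr(sub[target], sub[col]).statistic if len(sub) > 2 else np.nan
        rows.append({"factor": col, "spearman": rho, "abs_spearman": abs(rho)})
    return (
        pd.DataFrame(rows)
        .sort_values("abs_spearman", ascending=False)
        .reset_index(drop=True)
    )
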