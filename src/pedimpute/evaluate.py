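"""Leave-one-out masking cross-validation and imputation-quality metrics.

One reference individual at a time has its sequence genotypes masked,
keeping only its chip genotypes, and is imputed from the remaining
reference. Quality is summarised per individual x chromosome (Propi: the
proportion of genotypes correctly imputed; Cori: Pearson correlation of true
vs imputed dosages; lbPropi: the frequency-fill lower bound) and per SNP
(Props, Cors, the chance-corrected cProps and lbProps, with Ni the number of
individuals carrying a called truth genotype at the SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .core import MISSING, GenotypeMatrix, HaplotypeSet, Pedigree
from .imputers import FamilyLDImputer, FrequencyFillImputer, ImputationResult


@dataclass
class MaskingScheme:
    """Reference ids evaluated in turn plus optional extra target ids that
    are imputed in every fold without ever entering the reference."""

    reference_ids: list[str]
    held_out: str
    extra_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.held_out not in self.reference_ids:
            raise ValueError("held-out id must be one of the reference ids")
        overlap = set(self.extra_ids) & set(self.reference_ids)
        if overlap:
            raise ValueError(f"extra ids must not be reference ids: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Elementary metrics


def prop_match(truth: np.ndarray, imputed: np.ndarray, mode: str = "dosage") -> float:
    """Proportion of correctly imputed genotypes over called truth cells.

    ``mode="dosage"`` scores the indicator 1[g == g_hat]; ``mode="allele"``
    scores (2 - |g - g_hat|) / 2 per genotype, crediting half-right
    heterozygote calls. NA (nan) when no truth cell is called.
    """
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    called = truth != MISSING
    m = int(called.sum())
    if m == 0:
        return float("nan")
    t = truth[called].astype(np.int64)
    i = imputed[called].astype(np.int64)
    if mode == "dosage":
        return float((t == i).mean())
    if mode == "allele":
        return float((2 - np.abs(t - i)).sum() / (2.0 * m))
    raise ValueError("mode must be 'dosage' or 'allele'")


def pearson_or_nan(truth: np.ndarray, imputed: np.ndarray) -> float:
    """Pearson correlation of dosages over called truth cells; NA when either
    vector is constant (zero variance)."""
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    called = truth != MISSING
    t = truth[called].astype(float)
    i = imputed[called].astype(float)
    if t.size < 2 or t.std() == 0 or i.std() == 0:
        return float("nan")
    return float(np.corrcoef(t, i)[0, 1])


def prop_by_individual(
    truth_row: np.ndarray,
    imputed_row: np.ndarray,
    chrom: np.ndarray | None = None,
    mode: str = "dosage",
) -> float | pd.Series:
    """Propi: per chromosome when ``chrom`` is given, else genome-wide."""
    if chrom is None:
        return prop_match(truth_row, imputed_row, mode)
    chrom = np.asarray(chrom)
    return pd.Series(
        {
            c: prop_match(truth_row[chrom == c], imputed_row[chrom == c], mode)
            for c in pd.unique(chrom)
        }
    )


def cor_by_individual(
    truth_row: np.ndarray,
    imputed_row: np.ndarray,
    chrom: np.ndarray | None = None,
) -> float | pd.Series:
    """Cori: Pearson correlation of true vs imputed dosages."""
    if chrom is None:
        return pearson_or_nan(truth_row, imputed_row)
    chrom = np.asarray(chrom)
    return pd.Series(
        {
            c: pearson_or_nan(truth_row[chrom == c], imputed_row[chrom == c])
            for c in pd.unique(chrom)
        }
    )


def prop_by_snp(truth_col: np.ndarray, imputed_col: np.ndarray,
                mode: str = "dosage") -> tuple[float, int]:
    """(Props, Ni): proportion correct across individuals with called truth."""
    truth_col = np.asarray(truth_col)
    ni = int((truth_col != MISSING).sum())
    return prop_match(truth_col, imputed_col, mode), ni


def chance_corrected_prop(
    props: float,
    ref_freqs: tuple[float, float, float],
    val_freqs: tuple[float, float, float],
) -> float:
    """cProps = (Props - chance) / (1 - chance) with chance the probability
    of agreeing by drawing genotypes from the two frequency triples."""
    for tri in (ref_freqs, val_freqs):
        if abs(sum(tri) - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")
    chance = sum(p * q for p, q in zip(ref_freqs, val_freqs))
    if chance >= 1.0 - 1e-12:
        return float("nan")
    return (props - chance) / (1.0 - chance)


# ---------------------------------------------------------------------------
# LOO engine


@dataclass
class LOOResult:
    """Aligned truth and imputed matrices over all held-out individuals.

    ``extra_imputed`` holds the per-fold consensus (rounded mean dosage) for
    any extra chip-only targets imputed alongside every fold.
    """

    truth: GenotypeMatrix
    imputed: GenotypeMatrix
    imputed_haps: HaplotypeSet | None
    provenance: np.ndarray
    extra_imputed: GenotypeMatrix | None = None


def loo_cross_validate(
    reference: HaplotypeSet,
    chip: GenotypeMatrix,
    ped: Pedigree | None,
    imputer,
    seed: int = 0,
    extra_ids: list[str] | None = None,
) -> LOOResult:
    """Mask each reference individual's sequence genotypes in turn, impute it
    from the remaining reference using its chip genotypes, and collect the
    imputed rows against the truth.

    ``imputer`` is an unfitted estimator (cloned and refitted per fold, with
    a fold-specific random_state derived from ``seed``). ``extra_ids``
    (chip-only targets, e.g. additional unrelated accessions) are imputed in
    every fold; their per-fold imputations are averaged into a single
    consensus row appended to the output.
    """
    ref_ids = list(reference.samples)
    truth_gm = reference.to_genotype_matrix()
    n_sites = reference.n_sites
    extra_ids = list(extra_ids or [])
    bad = set(extra_ids) & set(ref_ids)
    if bad:
        raise ValueError(f"extra ids overlap reference: {sorted(bad)}")
    n_out = len(ref_ids) + len(extra_ids)
    imputed = np.zeros((n_out, n_sites), dtype=np.int8)
    prov = np.zeros((n_out, n_sites), dtype=np.uint8)
    hap_out = np.zeros((n_out, 2, n_sites), dtype=np.uint8)
    have_haps = True
    extra_sum = np.zeros((len(extra_ids), n_sites), dtype=np.float64)

    for fold, held in enumerate(ref_ids):
        rest = [s for s in ref_ids if s != held]
        ref_fold = reference.take_samples(rest)
        targets = [held] + extra_ids
        target_chip = chip.take_samples(targets)
        est = clone(imputer)
        est.set_params(random_state=(seed * 1009 + fold) % (2**31 - 1))
        est.fit(ref_fold, ped)
        res: ImputationResult = est.transform(target_chip)
        if res.imputed.n_sites != n_sites:
            raise RuntimeError(f"imputer failure in fold {fold} ({held})")
        imputed[fold] = res.imputed.dosage[0]
        prov[fold] = res.provenance[0]
        if res.haplotypes is not None:
            hap_out[fold] = res.haplotypes.hap[0]
        else:
            have_haps = False
        if extra_ids:
            extra_sum += res.imputed.dosage[1:]
    extra_gm = None
    if extra_ids:
        # consensus over folds: rounded mean dosage
        rows = np.clip(np.rint(extra_sum / len(ref_ids)), 0, 2).astype(np.int8)
        extra_gm = GenotypeMatrix(
            samples=extra_ids, sites=reference.sites, dosage=rows, phased=False
        )
    imputed = imputed[: len(ref_ids)]
    prov = prov[: len(ref_ids)]
    hap_out = hap_out[: len(ref_ids)]
    imputed_gm = GenotypeMatrix(
        samples=ref_ids, sites=reference.sites, dosage=imputed, phased=have_haps
    )
    haps = (
        HaplotypeSet(samples=ref_ids, sites=reference.sites, hap=hap_out)
        if have_haps
        else None
    )
    return LOOResult(truth=truth_gm, imputed=imputed_gm, imputed_haps=haps,
                     provenance=prov, extra_imputed=extra_gm)


# ---------------------------------------------------------------------------
# Quality tables


def quality_by_individual(
    loo: LOOResult, ped: Pedigree | None = None, mode: str = "dosage"
) -> pd.DataFrame:
    """Per-individual x chromosome table with Propi and Cori."""
    chrom = loo.truth.sites["chrom"].to_numpy()
    rows = []
    for i, sample_id in enumerate(loo.truth.samples):
        t = loo.truth.dosage[i]
        g = loo.imputed.dosage[i]
        for c in pd.unique(chrom):
            mask = chrom == c
            rows.append(
                {
                    "id": sample_id,
                    "chrom": c,
                    "class": ped.klass(sample_id) if ped is not None and sample_id in ped else "",
                    "Propi": prop_match(t[mask], g[mask], mode),
                    "Cori": pearson_or_nan(t[mask], g[mask]),
                }
            )
    return pd.DataFrame(rows)


def _genotype_freqs(col: np.ndarray) -> tuple[float, float, float]:
    called = col != MISSING
    n = max(int(called.sum()), 1)
    return tuple(float(((col == g) & called).sum()) / n for g in (0, 1, 2))


def quality_by_snp(loo: LOOResult, reference: HaplotypeSet | GenotypeMatrix,
                   mode: str = "dosage") -> pd.DataFrame:
    """Per-SNP table: Ni, Props, Cors (NA where monomorphic), cProps.

    Reference genotype frequencies come from the reference panel truth;
    validation frequencies from the imputed genotypes of the evaluated
    folds, following the chance-correction construction.
    """
    truth = loo.truth.dosage
    imp = loo.imputed.dosage
    ref_dos = reference.dosage() if isinstance(reference, HaplotypeSet) else reference.dosage
    n_sites = truth.shape[1]
    called = truth != MISSING
    ni = called.sum(axis=0)
    agree = (called & (truth == imp)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        props = np.where(ni > 0, agree / np.maximum(ni, 1), np.nan)
    # vectorised genotype frequencies
    def freqs(mat: np.ndarray, valid: np.ndarray) -> np.ndarray:
        n = np.maximum(valid.sum(axis=0), 1)
        return np.stack(
            [((mat == g) & valid).sum(axis=0) / n for g in (0, 1, 2)]
        )  # 3 x sites
    p_ref = freqs(ref_dos, ref_dos != MISSING)
    q_val = freqs(imp, called)
    chance = (p_ref * q_val).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cprops = np.where(chance < 1.0 - 1e-12,
                          (props - chance) / (1.0 - chance), np.nan)
    cors = np.full(n_sites, np.nan)
    tf = truth.astype(float)
    gf = imp.astype(float)
    tm = np.where(called, tf, np.nan)
    gm_ = np.where(called, gf, np.nan)
    with np.errstate(invalid="ignore"):
        tmean = np.nanmean(tm, axis=0)
        gmean = np.nanmean(gm_, axis=0)
        tstd = np.nanstd(tm, axis=0)
        gstd = np.nanstd(gm_, axis=0)
        cov = np.nanmean((tm - tmean) * (gm_ - gmean), axis=0)
        ok = (tstd > 0) & (gstd > 0) & (ni >= 2)
        cors[ok] = (cov / (tstd * gstd))[ok]
    return pd.DataFrame(
        {
            "chrom": loo.truth.sites["chrom"].to_numpy(),
            "pos": loo.truth.sites["pos"].to_numpy(),
            "Ni": ni,
            "Props": props,
            "Cors": cors,
            "cProps": cprops,
        }
    )


def lower_bound_metrics(
    reference: HaplotypeSet,
    chip: GenotypeMatrix,
    ped: Pedigree | None = None,
    seed: int = 0,
    mode: str = "allele",
) -> tuple[pd.DataFrame, pd.DataFrame, LOOResult]:
    """Run the frequency random-fill imputer in the identical LOO scheme and
    score it: (per-individual lbPropi table, per-SNP lbProps table, raw LOO)."""
    imputer = FrequencyFillImputer(mode=mode, random_state=seed)
    loo = loo_cross_validate(reference, chip, ped, imputer, seed=seed)
    qi = quality_by_individual(loo, ped).rename(
        columns={"Propi": "lbPropi", "Cori": "lbCori"}
    )
    qs = quality_by_snp(loo, reference).rename(
        columns={"Props": "lbProps", "Cors": "lbCors", "cProps": "lbcProps"}
    )
    return qi, qs, loo


def select_high_quality_snps(
    qt: pd.DataFrame, props_min: float = 0.90, cprops_min: float = 0.80
) -> pd.DataFrame:
    """Sites with Props > props_min AND cProps > cprops_min (strict >);
    rows with NA cProps are excluded."""
    keep = (qt["Props"] > props_min) & (qt["cProps"] > cprops_min)
    keep &= qt["cProps"].notna() & qt["Props"].notna()
    return qt.loc[keep].reset_index(drop=True)


def evaluate_imputation(
    reference: HaplotypeSet,
    chip: GenotypeMatrix,
    ped: Pedigree | None = None,
    window_sizes: tuple[int, ...] = (64, 16, 4),
    overlap: float = 0.5,
    seed: int = 0,
) -> dict:
    """Full evaluation: family/LD LOO + frequency-fill lower bound, merged
    per-individual and per-SNP tables. Returns a dict of DataFrames/results."""
    imputer = FamilyLDImputer(window_sizes=window_sizes, overlap=overlap,
                              random_state=seed)
    loo = loo_cross_validate(reference, chip, ped, imputer, seed=seed)
    qi = quality_by_individual(loo, ped)
    qs = quality_by_snp(loo, reference)
    lb_qi, lb_qs, lb_loo = lower_bound_metrics(reference, chip, ped, seed=seed)
    qi = qi.merge(lb_qi[["id", "chrom", "lbPropi"]], on=["id", "chrom"])
    qs = qs.merge(lb_qs[["chrom", "pos", "lbProps"]], on=["chrom", "pos"])
    return {
        "individual": qi,
        "snp": qs,
        "loo": loo,
        "lb_loo": lb_loo,
    }
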