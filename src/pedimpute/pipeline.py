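"""End-to-end study runner: simulate -> filter -> impute -> evaluate ->
factors -> LD, with deterministic tab-separated reports.

This is the programmatic core of the ``run-all`` subcommand and of the
reproduction script; each stage is also reachable on its own through the
stage modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HaplotypeSet
from .evaluate import evaluate_imputation, select_high_quality_snps
from .factors import assemble_factor_table, rank_factor_correlations, snp_factors
from .filtering import run_filter_cascade
from .imputers import fill_chip_missing, target_site_indices
from .ld import pairwise_ld, weighted_mean_dprime
from .simulate import SimConfig, add_genotype_errors, simulate_study

FLOAT_FMT = "%.6g"


@dataclass
class StudyResult:
    config: SimConfig
    filter_report: pd.DataFrame
    chip_report: pd.DataFrame
    quality_individual: pd.DataFrame
    quality_snp: pd.DataFrame
    factor_table: pd.DataFrame
    factor_ranking: pd.DataFrame
    ld_profile: pd.DataFrame
    summary: dict


def run_study(
    cfg: SimConfig,
    caller_error_rate: float = 0.005,
    window_sizes: tuple[int, ...] = (64, 16, 4),
    overlap: float = 0.5,
    ld_max_distance_bp: int = 2_000_000,
    ld_max_sites_per_chrom: int = 600,
    window_bp: int = 500_000,
) -> StudyResult:
    """Run the whole evaluation under one seed.

    Two error-injected copies of the sequenced panel stand in for the two
    variant callers feeding the filter cascade; the evaluation then runs on
    the cascade's surviving sites with the phased truth as reference.
    """
    seed = cfg.seed
    study = simulate_study(cfg)
    ped = study.pedigree

    # dual-caller filter cascade on the sequenced panel
    rng = np.random.default_rng(seed + 11)
    seq_a = add_genotype_errors(study.seq_ref, caller_error_rate, rng=rng)
    seq_b = add_genotype_errors(study.seq_ref, caller_error_rate, rng=rng)
    chip_ref_raw = study.chip_all.take_samples(study.reference_ids)
    seq_f, chip_f, seq_rep, chip_rep = run_filter_cascade(
        seq_a, seq_b, chip_ref_raw, ped
    )

    # evaluation panels: phased truth restricted to surviving sites
    keep_seq = target_site_indices(study.seq_ref.sites, seq_f)
    haps_ref = study.haps_ref.take_sites(keep_seq)
    # chip sites must survive in both panels
    chip_in_seq = target_site_indices(seq_f.sites, chip_f) >= 0
    chip_f = chip_f.take_sites(np.flatnonzero(chip_in_seq))
    chip_filled, _ = fill_chip_missing(chip_f, ped, seed=seed + 13)

    ev = evaluate_imputation(
        haps_ref, chip_filled, ped,
        window_sizes=window_sizes, overlap=overlap, seed=seed,
    )
    qi, qs = ev["individual"], ev["snp"]

    seq_truth = haps_ref.to_genotype_matrix()
    seq_truth.sites = seq_f.sites  # carry qual/site_depth through
    fac = snp_factors(
        GenotypeMatrix(
            samples=seq_truth.samples, sites=seq_f.sites,
            dosage=seq_truth.dosage, phased=True,
        ),
        chip_f.sites, window_bp=window_bp,
    )
    table = assemble_factor_table(qs, fac)
    ranking = rank_factor_correlations(
        table, target="Props", factor_cols=("RatioDensity", "DEPTH", "QUAL")
    )

    # LD: chip (true phase) vs imputed sequence on high-quality sites
    selected = select_high_quality_snps(qs)
    chip_idx_in_ref = target_site_indices(haps_ref.sites, chip_f)
    chip_haps = haps_ref.take_sites(chip_idx_in_ref)
    chip_pairs = pairwise_ld(chip_haps, ld_max_distance_bp, seed=seed)
    seq_pairs = pairwise_ld(
        ev["loo"].imputed_haps,
        ld_max_distance_bp,
        site_filter=selected[["chrom", "pos"]],
        max_sites_per_chrom=ld_max_sites_per_chrom,
        seed=seed,
    )
    prof_chip = weighted_mean_dprime(chip_pairs, window_bp=window_bp)
    prof_seq = weighted_mean_dprime(seq_pairs, window_bp=window_bp)
    prof_chip["panel"] = "chip"
    prof_seq["panel"] = "seq"
    ld_profile = pd.concat([prof_chip, prof_seq], ignore_index=True)

    def wmean(pairs: pd.DataFrame) -> float:
        if pairs.empty or pairs["maf_product"].sum() == 0:
            return float("nan")
        return float(np.average(pairs["dprime"], weights=pairs["maf_product"]))

    propi_mean = qi.groupby("class")["Propi"].mean()
    summary = {
        "seed": seed,
        "n_sites_after_filter": int(seq_f.n_sites),
        "n_chip_after_qc": int(chip_f.n_sites),
        "mean_propi": float(qi["Propi"].mean()),
        "mean_lbpropi": float(qi["lbPropi"].mean()),
        "mean_cori": float(qi["Cori"].mean()),
        "mean_propi_by_class": {k: float(v) for k, v in propi_mean.items()},
        "propi_cori_r": float(qi[["Propi", "Cori"]].dropna().corr().iloc[0, 1]),
        "n_high_quality_snps": int(len(selected)),
        "frac_high_quality_snps": float(len(selected) / max(len(qs), 1)),
        "mean_dprime_chip": wmean(chip_pairs),
        "mean_dprime_seq": wmean(seq_pairs),
        "top_factor": str(ranking.iloc[0]["factor"]) if len(ranking) else "",
    }
    return StudyResult(
        config=cfg,
        filter_report=seq_rep.to_frame(),
        chip_report=chip_rep.to_frame(),
        quality_individual=qi,
        quality_snp=qs,
        factor_table=table,
        factor_ranking=ranking,
        ld_profile=ld_profile,
        summary=summary,
    )


def write_study_result(result: StudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    result.chip_report.to_csv(out / "chip_report.tsv", sep="\t", index=False)
    result.quality_individual.to_csv(
        out / "qual_individual.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    result.quality_snp.to_csv(
        out / "qual_snp.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    result.factor_table.to_csv(
        out / "factors.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    result.factor_ranking.to_csv(
        out / "factor_ranking.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    result.ld_profile.to_csv(
        out / "ld_profile.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
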