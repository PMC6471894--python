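"""Post-calling filter cascade and chip QC.

The sequence panel goes through, in order: a quality/allele filter, removal
of monomorphic sites, positional intersection of the two variant callers, a
per-site caller-concordance filter and a Mendelian-segregation filter. The
chip panel gets a missingness filter followed by the same Mendelian check.
Each step appends a row to a :class:`FilterReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Pedigree
from .vcfio import intersect_panels

logger = logging.getLogger(__name__)


@dataclass
class FilterStep:
    name: str
    sites_in: int
    sites_removed: int

    @property
    def sites_out(self) -> int:
        return self.sites_in - self.sites_removed


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, sites_in: int, sites_removed: int) -> None:
        step = FilterStep(name, sites_in, sites_removed)
        if self.steps and self.steps[-1].sites_out != sites_in:
            raise ValueError(
                f"step {name!r} input {sites_in} does not chain from previous "
                f"output {self.steps[-1].sites_out}"
            )
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.name for s in self.steps],
                "sites_in": [s.sites_in for s in self.steps],
                "sites_removed": [s.sites_removed for s in self.steps],
                "sites_out": [s.sites_out for s in self.steps],
            }
        )


def filter_quality(
    gm: GenotypeMatrix,
    min_qual: float = 30.0,
    min_mean_depth: float = 2.0,
    max_alleles: int = 3,
    min_alleles: int = 2,
    no_missing: bool = True,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterStep]:
    """Keep sites with qual >= min_qual, mean depth >= min_mean_depth,
    allele count within bounds and (optionally) zero missing genotypes."""
    qual = gm.sites["qual"].to_numpy(dtype=float)
    keep = qual >= min_qual
    if gm.depth is not None:
        keep &= gm.depth.mean(axis=0) >= min_mean_depth
    else:
        keep &= gm.sites["site_depth"].to_numpy(dtype=float) / max(gm.n_samples, 1) >= min_mean_depth
    n_alleles = 1 + gm.sites["alts"].astype(str).str.split(",").str.len().to_numpy()
    keep &= (n_alleles >= min_alleles) & (n_alleles <= max_alleles)
    if no_missing:
        keep &= ~(gm.dosage == MISSING).any(axis=0)
    out = gm.take_sites(np.flatnonzero(keep))
    step = FilterStep("quality", gm.n_sites, int((~keep).sum()))
    if report is not None:
        report.steps.append(step)
    if out.n_sites == 0:
        logger.warning("filter_quality removed every site")
    return out, step


def drop_monomorphic(
    gm: GenotypeMatrix, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterStep]:
    """Remove sites whose non-missing dosages are all identical (including
    all-homozygous-alternative sites that differ only from the external
    reference genome); all-missing sites are vacuously monomorphic."""
    dos = gm.dosage
    called = dos != MISSING
    any_called = called.any(axis=0)
    first = np.where(any_called, dos[called.argmax(axis=0), np.arange(gm.n_sites)], 0)
    poly = (called & (dos != first[None, :])).any(axis=0)
    n_vacuous = int((~any_called).sum())
    if n_vacuous:
        logger.info("drop_monomorphic: %d all-missing sites removed", n_vacuous)
    out = gm.take_sites(np.flatnonzero(poly))
    step = FilterStep("monomorphic", gm.n_sites, int((~poly).sum()))
    if report is not None:
        report.steps.append(step)
    return out, step


def caller_concordance_filter(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    min_concordance: float = 0.95,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterStep]:
    """Keep shared positions where the two callers agree for at least
    ``min_concordance`` of the samples; genotypes are taken from caller a."""
    if set(a.samples) != set(b.samples):
        raise ValueError("caller panels must share the same sample set")
    b = b.take_samples(a.samples)
    inter = intersect_panels(a, b)
    da = a.dosage[:, inter.idx_a]
    db = b.dosage[:, inter.idx_b]
    both = (da != MISSING) & (db != MISSING)
    agree = both & (da == db)
    denom = np.maximum(both.sum(axis=0), 1)
    conc = agree.sum(axis=0) / denom
    informative = both.any(axis=0)
    keep = informative & (conc >= min_concordance)
    out = a.take_sites(inter.idx_a[keep])
    step = FilterStep("caller_concordance", a.n_sites, a.n_sites - out.n_sites)
    if report is not None:
        report.steps.append(step)
    return out, step


# --- Mendelian consistency -------------------------------------------------


def _pair_from_dosage(d: int) -> tuple[int, int]:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[d]


def _consistent(child: tuple[int, int], sire: tuple[int, int] | None,
                dam: tuple[int, int] | None) -> bool:
    """Allele-set rule: the child's two alleles can be partitioned so one is
    carried by the sire and the other by the dam; duos require one shared
    allele; a missing parent constrains nothing."""
    c1, c2 = child
    if sire is None and dam is None:
        return True
    if sire is None or dam is None:
        par = sire if sire is not None else dam
        return c1 in par or c2 in par
    return (c1 in sire and c2 in dam) or (c2 in sire and c1 in dam)


# dosage-level consistency table for biallelic sites, indexed
# [sire+1, dam+1, child+1] with MISSING mapped to index 0 (always consistent)
_TRIO_OK = np.ones((4, 4, 4), dtype=bool)
for _s, _d, _c in product(range(3), range(3), range(3)):
    _TRIO_OK[_s + 1, _d + 1, _c + 1] = _consistent(
        _pair_from_dosage(_c), _pair_from_dosage(_s), _pair_from_dosage(_d)
    )
for _p, _c in product(range(3), range(3)):
    ok = _consistent(_pair_from_dosage(_c), _pair_from_dosage(_p), None)
    _TRIO_OK[_p + 1, 0, _c + 1] = ok
    _TRIO_OK[0, _p + 1, _c + 1] = ok


def mendelian_violations(gm: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Boolean per-site flag: some trio/duo is Mendelian-inconsistent.

    Biallelic sites are checked on dosage (equivalent to the allele-set rule
    under two alleles); sites with recorded multi-allelic genotypes are
    checked on allele identity.
    """
    sample_set = set(gm.samples)
    trios = ped.trios(available=sample_set)
    bad = np.zeros(gm.n_sites, dtype=bool)
    if not trios:
        return bad
    idx = {s: i for i, s in enumerate(gm.samples)}
    n_alleles = 1 + gm.sites["alts"].astype(str).str.split(",").str.len().to_numpy()
    multi = n_alleles > 2
    dos = gm.dosage
    for child, sire, dam in trios:
        ci = idx[child]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        s_row = dos[si] + 1 if si is not None else np.zeros(gm.n_sites, dtype=np.int8)
        d_row = dos[di] + 1 if di is not None else np.zeros(gm.n_sites, dtype=np.int8)
        c_row = dos[ci] + 1
        ok = _TRIO_OK[s_row, d_row, c_row]
        bad |= ~ok & ~multi
    if multi.any() and gm.alleles is not None:
        al = gm.alleles
        for j in np.flatnonzero(multi):
            for child, sire, dam in trios:
                cpair = al[idx[child], j, :]
                if (cpair < 0).any():
                    continue

                def pair(i):
                    if i is None:
                        return None
                    p = al[idx[i], j, :]
                    return None if (p < 0).any() else tuple(int(x) for x in p)

                if not _consistent(
                    (int(cpair[0]), int(cpair[1])), pair(sire), pair(dam)
                ):
                    bad[j] = True
                    break
    return bad


def mendelian_filter(
    gm: GenotypeMatrix, ped: Pedigree, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterStep]:
    """Remove sites where any available trio or duo violates Mendelian
    segregation; trios with a missing member are non-informative there."""
    bad = mendelian_violations(gm, ped)
    out = gm.take_sites(np.flatnonzero(~bad))
    step = FilterStep("mendelian", gm.n_sites, int(bad.sum()))
    if report is not None:
        report.steps.append(step)
    return out, step


def chip_qc_filter(
    chip: GenotypeMatrix,
    ped: Pedigree,
    max_missing: float = 0.90,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterStep]:
    """Chip QC: drop markers missing in more than ``max_missing`` of the
    samples (strict >), then apply the Mendelian filter."""
    miss = (chip.dosage == MISSING).mean(axis=0)
    keep = miss <= max_missing
    mid = chip.take_sites(np.flatnonzero(keep))
    bad = mendelian_violations(mid, ped)
    out = mid.take_sites(np.flatnonzero(~bad))
    step = FilterStep("chip_qc", chip.n_sites, chip.n_sites - out.n_sites)
    if report is not None:
        report.steps.append(step)
    return out, step


def run_filter_cascade(
    seq_a: GenotypeMatrix,
    seq_b: GenotypeMatrix,
    chip: GenotypeMatrix,
    ped: Pedigree,
    min_qual: float = 30.0,
    min_mean_depth: float = 2.0,
    max_alleles: int = 3,
    min_concordance: float = 0.95,
    chip_max_missing: float = 0.90,
) -> tuple[GenotypeMatrix, GenotypeMatrix, FilterReport, FilterReport]:
    """Apply the whole cascade; returns (seq, chip, seq_report, chip_report)."""
    seq_report = FilterReport()
    a, _ = filter_quality(
        seq_a, min_qual=min_qual, min_mean_depth=min_mean_depth,
        max_alleles=max_alleles, report=seq_report,
    )
    b, _ = filter_quality(
        seq_b, min_qual=min_qual, min_mean_depth=min_mean_depth,
        max_alleles=max_alleles,
    )
    a, _ = drop_monomorphic(a, report=seq_report)
    b, _ = drop_monomorphic(b)
    a, _ = caller_concordance_filter(a, b, min_concordance=min_concordance,
                                     report=seq_report)
    seq_out, _ = mendelian_filter(a, ped, report=seq_report)
    chip_report = FilterReport()
    chip_report.steps.append(FilterStep("input", chip.n_sites, 0))
    chip_out, _ = chip_qc_filter(chip, ped, max_missing=chip_max_missing,
                                 report=chip_report)
    return seq_out, chip_out, seq_report, chip_report
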