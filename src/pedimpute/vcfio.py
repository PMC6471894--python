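"""Readers and writers for the pipeline's exchange formats.

VCF 4.2 is the exchange format for genotype panels (GT, per-sample DP and the
site QUAL column are round-tripped); pedigrees travel as tab-separated
``id/sire/dam/class`` tables. Reading uses cyvcf2; writing emits plain VCF
text, which keeps the deliverables diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    Pedigree,
    PedigreeRecord,
)

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


def read_vcf(
    path: str | Path, require_phase: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, HaplotypeSet]:
    """Read a VCF into a GenotypeMatrix (plus HaplotypeSet when phased).

    Dosage is the count of non-reference alleles; both alternative alleles of
    a triallelic site count as non-reference. Sites with more than three
    alleles are rejected (logged with a count). Per-sample DP and the QUAL
    column are captured when present. With ``require_phase`` the genotypes
    must all be phased ('|' separators) and biallelic; the per-haplotype
    alleles are returned alongside.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts_l: list[str] = []
    quals: list[float] = []
    dosage_rows: list[np.ndarray] = []
    allele_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_rejected = 0
    any_depth = False

    for var in vcf:
        alts = [a for a in (var.ALT or []) if a]
        if 1 + len(alts) > 3:
            n_rejected += 1
            continue
        if len(alts) == 0:
            n_rejected += 1
            continue
        try:
            gts = var.genotypes  # list of [a1, a2, ..., phased]
        except Exception as exc:  # pragma: no cover - cyvcf2 raises rarely
            raise VcfParseError(f"malformed record at {var.CHROM}:{var.POS}") from exc
        pair = np.full((n, 2), MISSING, dtype=np.int8)
        phased_flags = np.zeros(n, dtype=bool)
        for j, gt in enumerate(gts):
            if len(gt) < 3:
                raise VcfParseError(
                    f"non-diploid genotype for sample {samples[j]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            a1, a2, ph = gt[0], gt[1], gt[-1]
            if len(gt) != 3:
                raise VcfParseError(
                    f"ploidy != 2 for sample {samples[j]} at {var.CHROM}:{var.POS}"
                )
            pair[j, 0] = a1 if a1 >= 0 else MISSING
            pair[j, 1] = a2 if a2 >= 0 else MISSING
            phased_flags[j] = bool(ph)
        if require_phase:
            called = (pair >= 0).all(axis=1)
            if not phased_flags[called].all():
                raise VcfParseError(
                    f"phase required but unphased genotype at {var.CHROM}:{var.POS}"
                )
            if len(alts) > 1:
                raise VcfParseError(
                    f"phased haplotypes require biallelic sites ({var.CHROM}:{var.POS})"
                )
            hap_rows.append(np.where(pair >= 0, pair, 0).astype(np.uint8))
        dos = np.where(
            (pair >= 0).all(axis=1), (pair > 0).sum(axis=1), MISSING
        ).astype(np.int8)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = np.asarray(dp).reshape(n).astype(float)
            dp[dp < 0] = 0.0
            any_depth = True
        else:
            dp = np.zeros(n)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts_l.append(",".join(alts))
        quals.append(float(var.QUAL) if var.QUAL is not None else 0.0)
        dosage_rows.append(dos)
        allele_rows.append(pair)
        depth_rows.append(dp)

    if n_rejected:
        logger.info("read_vcf(%s): rejected %d sites with >3 alleles", path, n_rejected)

    m = len(chroms)
    dosage = (
        np.stack(dosage_rows, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    )
    depth = np.stack(depth_rows, axis=1) if (m and any_depth) else None
    alleles = (
        np.stack(allele_rows, axis=1) if m else np.zeros((n, 0, 2), dtype=np.int8)
    )
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.array(poss, dtype=np.int64),
            "ref": refs,
            "alts": alts_l,
            "qual": quals,
            "site_depth": depth.sum(axis=0) if depth is not None else np.zeros(m),
        }
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosage = dosage[:, order]
    alleles = alleles[:, order]
    if depth is not None:
        depth = depth[:, order]
    gm = GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=dosage,
        phased=require_phase,
        depth=depth,
        alleles=alleles,
    )
    if require_phase:
        # cyvcf2 yields [a1, a2]; these are the two haplotypes of each sample
        hap = (
            np.stack(hap_rows, axis=2)[:, :, order]
            if m
            else np.zeros((n, 2, 0), dtype=np.uint8)
        )
        hs = HaplotypeSet(samples=samples, sites=sites, hap=hap)
        return gm, hs
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path, haps: HaplotypeSet | None = None) -> Path:
    """Write a GenotypeMatrix as VCF 4.2 (GT, per-sample DP when available).

    Round-trip identity holds for dosages, coordinates, QUAL, DP and phase.
    When ``haps`` is given (or ``gm.alleles`` is present) the written GT
    carries allele identity; otherwise heterozygotes are written as 0/1
    against the first alternative allele.
    """
    path = Path(path)
    sep = "|" if gm.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dp = gm.depth is not None
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT:DP" if has_dp else "GT"
        for i in range(gm.n_sites):
            row = gm.sites.iloc[i]
            qual = row.get("qual", 0.0)
            qual_s = f"{qual:g}" if qual == qual else "."
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                str(row.get("ref", "A")),
                str(row.get("alts", "T")),
                qual_s,
                "PASS",
                ".",
                fmt,
            ]
            for j in range(gm.n_samples):
                if haps is not None:
                    a, b = int(haps.hap[j, 0, i]), int(haps.hap[j, 1, i])
                    gt = f"{a}{sep}{b}"
                    if gm.dosage[j, i] == MISSING:
                        gt = f".{sep}."
                elif gm.alleles is not None:
                    a, b = gm.alleles[j, i, :]
                    gt = f".{sep}." if (a < 0 or b < 0) else f"{a}{sep}{b}"
                else:
                    d = gm.dosage[j, i]
                    gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}.get(
                        int(d), f".{sep}."
                    )
                if has_dp:
                    gt += f":{int(round(gm.depth[j, i]))}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")
    return path


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a tab-separated pedigree with header id, sire, dam, class."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "sire", "dam", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    records = [
        PedigreeRecord(
            id=row["id"],
            sire=row["sire"] or None,
            dam=row["dam"] or None,
            klass=row["class"],
        )
        for _, row in df.iterrows()
    ]
    return Pedigree(records=records)


def write_pedigree(ped: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    ped.to_frame().to_csv(path, sep="\t", index=False)
    return path


@dataclass
class PanelIntersection:
    """Positions shared by two panels, matched on (chrom, pos)."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_mismatch: pd.DataFrame  # shared positions whose allele strings differ

    def __len__(self) -> int:
        return len(self.idx_a)


def intersect_panels(a: GenotypeMatrix, b: GenotypeMatrix) -> PanelIntersection:
    """Index map of (chrom, pos) shared by both panels plus an allele report.

    Symmetric in the set of shared coordinates. Allele-string mismatches
    (ref or alts differing at a shared position) are flagged, not dropped:
    indels mapped against a foreign reference can disagree in representation.
    """
    ka = a.site_keys()
    kb = b.site_keys()
    common = ka.intersection(kb, sort=False)
    if len(common) == 0:
        logger.info("intersect_panels: empty intersection")
        empty = np.array([], dtype=np.int64)
        return PanelIntersection(
            idx_a=empty,
            idx_b=empty,
            chrom=np.array([], dtype=object),
            pos=empty,
            allele_mismatch=pd.DataFrame(columns=["chrom", "pos", "a", "b"]),
        )
    # preserve the sorted (chrom, pos) order of panel a
    idx_a = ka.get_indexer(common)
    order = np.argsort(idx_a)
    idx_a = idx_a[order]
    idx_b = kb.get_indexer(common)[order]
    sa = a.sites.iloc[idx_a]
    sb = b.sites.iloc[idx_b]
    astr = (sa["ref"].astype(str) + ">" + sa["alts"].astype(str)).to_numpy()
    bstr = (sb["ref"].astype(str) + ">" + sb["alts"].astype(str)).to_numpy()
    mm = astr != bstr
    mismatch = pd.DataFrame(
        {
            "chrom": sa["chrom"].to_numpy()[mm],
            "pos": sa["pos"].to_numpy()[mm],
            "a": astr[mm],
            "b": bstr[mm],
        }
    )
    return PanelIntersection(
        idx_a=np.asarray(idx_a),
        idx_b=np.asarray(idx_b),
        chrom=sa["chrom"].to_numpy(),
        pos=sa["pos"].to_numpy(),
        allele_mismatch=mismatch,
    )
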