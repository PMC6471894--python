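"""Genomic-region and mutation-type annotation profiling.

Classifies SNP positions against user-supplied gene models (GFF3 + FASTA)
into the familiar gene-annotation category system (exonic, splicing,
intronic, UTR5/UTR3, up/downstream, intergenic, with compound labels where
transcripts overlap) and, for coding variants, into mutation types
(synonymous / non-synonymous SNV, stop gain/loss, frameshift and
non-frameshift indels). Used to compare the annotation profile of a chip
panel against the denser imputed sequence panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq

REGION_CATEGORIES = [
    "downstream",
    "exonic",
    "intergenic",
    "intronic",
    "splicing",
    "exonic;splicing",
    "upstream",
    "UTR3",
    "UTR5",
    "UTR5;UTR3",
    "upstream;downstream",
]

MUTATION_TYPES = [
    "frameshift deletion",
    "frameshift insertion",
    "non-frameshift deletion",
    "non-frameshift insertion",
    "synonymous SNV",
    "non-synonymous SNV",
    "stop gain",
    "stop loss",
    "unclassified",
]


@dataclass
class GeneModel:
    """One transcript: 1-based inclusive exon and CDS intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for k in range(1, len(self.exons)):
            if self.exons[k][0] <= self.exons[k - 1][1]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for lo, hi in self.cds:
            if not any(e0 <= lo and hi <= e1 for e0, e1 in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS not contained in exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def in_exon(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.cds)


def read_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse transcripts (mRNA features with exon/CDS children) from GFF3."""
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        if not exons:
            exons = cds[:]
        models.append(
            GeneModel(
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def _classify_one(
    pos: int, model: GeneModel, upstream_bp: int, splice_bp: int
) -> str | None:
    """Category of ``pos`` with respect to a single transcript, or None."""
    if model.start <= pos <= model.end:
        near_boundary = False
        for k, (lo, hi) in enumerate(model.exons):
            if lo <= pos <= hi:
                # close to an exon/intron boundary (not a transcript end)?
                if (k > 0 and pos - lo < splice_bp) or (
                    k < len(model.exons) - 1 and hi - pos < splice_bp
                ):
                    near_boundary = True
                break
        if model.in_exon(pos):
            if model.in_cds(pos):
                return "exonic;splicing" if near_boundary else "exonic"
            if not model.cds:
                return "exonic"  # non-coding transcript
            cds_lo = model.cds[0][0]
            cds_hi = model.cds[-1][1]
            if pos < cds_lo:
                return "UTR5" if model.strand == "+" else "UTR3"
            if pos > cds_hi:
                return "UTR3" if model.strand == "+" else "UTR5"
            return "exonic"  # between CDS chunks inside an exon (rare)
        # intronic side: splicing when within splice_bp of an exon boundary
        for k in range(len(model.exons) - 1):
            intron_lo = model.exons[k][1] + 1
            intron_hi = model.exons[k + 1][0] - 1
            if intron_lo <= pos <= intron_hi:
                if pos - intron_lo < splice_bp or intron_hi - pos < splice_bp:
                    return "splicing"
                return "intronic"
        return "intronic"  # pragma: no cover - defensive
    five_prime = model.start if model.strand == "+" else model.end
    three_prime = model.end if model.strand == "+" else model.start
    if model.strand == "+":
        if 0 < five_prime - pos <= upstream_bp:
            return "upstream"
        if 0 < pos - three_prime <= upstream_bp:
            return "downstream"
    else:
        if 0 < pos - five_prime <= upstream_bp:
            return "upstream"
        if 0 < three_prime - pos <= upstream_bp:
            return "downstream"
    return None


# precedence of single-transcript labels, highest first
_PRECEDENCE = [
    "exonic;splicing",
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
]


def classify_region(
    chrom: str,
    pos: int,
    models: list[GeneModel],
    upstream_bp: int = 1000,
    splice_bp: int = 2,
) -> str:
    """Region category of a position, combining all overlapping transcripts.

    Per-transcript labels are merged by precedence (exonic > splicing > UTR
    > intronic > up/downstream > intergenic); opposite-strand overlaps yield
    the compound labels UTR5;UTR3 and upstream;downstream.
    """
    labels = set()
    for model in models:
        if model.chrom != chrom:
            continue
        lab = _classify_one(pos, model, upstream_bp, splice_bp)
        if lab is not None:
            labels.add(lab)
    if not labels:
        return "intergenic"
    if {"UTR5", "UTR3"} <= labels and not labels & {"exonic", "exonic;splicing",
                                                    "splicing"}:
        return "UTR5;UTR3"
    if {"upstream", "downstream"} <= labels and labels <= {"upstream", "downstream"}:
        return "upstream;downstream"
    for lab in _PRECEDENCE:
        if lab in labels:
            return lab
    return "intergenic"  # pragma: no cover


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    from pyfaidx import Fasta

    fa = Fasta(str(genome))
    return {name: str(fa[name][:]) for name in fa.keys()}


def classify_coding_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome,
) -> str:
    """Mutation type of a variant overlapping the transcript's CDS.

    SNVs are translated through the standard codon table (strand-aware);
    indels are frameshift when the length change is not a multiple of 3.
    Complex substitutions are 'unclassified'.
    """
    if len(ref) == len(alt) == 1:
        seqs = _load_genome(genome)
        if chrom not in seqs:
            return "unclassified"
        chrom_seq = seqs[chrom]
        segments = model.cds
        offset = None
        acc = 0
        for lo, hi in segments:
            if lo <= pos <= hi:
                offset = acc + (pos - lo)
                break
            acc += hi - lo + 1
        if offset is None:
            return "unclassified"
        cds_seq = "".join(chrom_seq[lo - 1: hi] for lo, hi in segments)
        alt_seq = list(cds_seq)
        alt_seq[offset] = alt
        alt_seq = "".join(alt_seq)
        if chrom_seq[pos - 1].upper() != ref.upper():
            return "unclassified"
        if model.strand == "-":
            cds_seq = str(Seq(cds_seq).reverse_complement())
            alt_seq = str(Seq(alt_seq).reverse_complement())
            offset = len(cds_seq) - offset - 1
        codon_i = offset // 3
        ref_codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
        alt_codon = alt_seq[3 * codon_i: 3 * codon_i + 3]
        if len(ref_codon) < 3:
            return "unclassified"
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return "synonymous SNV"
        if aa_alt == "*":
            return "stop gain"
        if aa_ref == "*":
            return "stop loss"
        return "non-synonymous SNV"
    delta = len(alt) - len(ref)
    if delta == 0:
        return "unclassified"
    kind = "insertion" if delta > 0 else "deletion"
    if abs(delta) % 3 != 0:
        return f"frameshift {kind}"
    return f"non-frameshift {kind}"


@dataclass
class AnnotationProfile:
    """Per-category counts and percentages (of total and of annotated)."""

    region: pd.DataFrame
    mutation: pd.DataFrame
    n_total: int
    n_annotated: int


def annotation_profile(
    sites: pd.DataFrame,
    models: list[GeneModel],
    genome=None,
    upstream_bp: int = 1000,
    splice_bp: int = 2,
) -> AnnotationProfile:
    """Classify every site; coding effects for exonic SNVs/indels when a
    genome sequence is supplied. ``sites`` needs chrom/pos (+ ref/alts for
    mutation typing)."""
    region_counts = {c: 0 for c in REGION_CATEGORIES}
    mutation_counts = {c: 0 for c in MUTATION_TYPES}
    genome_d = _load_genome(genome) if genome is not None else None
    has_alleles = {"ref", "alts"} <= set(sites.columns)
    for _, row in sites.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        cat = classify_region(chrom, pos, models, upstream_bp, splice_bp)
        region_counts[cat] += 1
        if cat in ("exonic", "exonic;splicing") and genome_d is not None and has_alleles:
            model = next(
                (m for m in models if m.chrom == chrom and m.in_cds(pos)), None
            )
            if model is None:
                continue
            alt = str(row["alts"]).split(",")[0]
            mut = classify_coding_effect(chrom, pos, str(row["ref"]), alt,
                                         model, genome_d)
            mutation_counts[mut] += 1
    n_total = len(sites)
    n_annot = n_total - region_counts["intergenic"]
    denom = max(n_total, 1)
    region = pd.DataFrame(
        {
            "category": REGION_CATEGORIES,
            "count": [region_counts[c] for c in REGION_CATEGORIES],
        }
    )
    region["pct_total"] = 100.0 * region["count"] / denom
    region["pct_annotated"] = 100.0 * region["count"] / max(n_annot, 1)
    mutation = pd.DataFrame(
        {
            "mutation_type": MUTATION_TYPES,
            "count": [mutation_counts[c] for c in MUTATION_TYPES],
        }
    )
    mutation["pct_total"] = 100.0 * mutation["count"] / denom
    return AnnotationProfile(
        region=region, mutation=mutation, n_total=n_total, n_annotated=n_annot
    )


def compare_profiles(a: AnnotationProfile, b: AnnotationProfile,
                     labels: tuple[str, str] = ("chip", "seq")) -> pd.DataFrame:
    """Side-by-side region percentages for two panels."""
    la, lb = labels
    out = a.region[["category", "count", "pct_total"]].rename(
        columns={"count": f"count_{la}", "pct_total": f"pct_{la}"}
    )
    out = out.merge(
        b.region[["category", "count", "pct_total"]].rename(
            columns={"count": f"count_{lb}", "pct_total": f"pct_{lb}"}
        ),
        on="category",
    )
    return out
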