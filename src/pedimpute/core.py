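"""Core domain types shared by every pipeline stage.

The common currency is the :class:`GenotypeMatrix` — samples × markers allelic
dosages (count of non-reference alleles, 0/1/2) with a missing sentinel — plus
the phased :class:`HaplotypeSet` and the :class:`Pedigree` that drives
simulation, Mendelian filtering and per-class reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Missing-genotype sentinel. Deliberately distinct from any valid dosage;
#: metrics and filters must skip it explicitly.
MISSING: int = -1

#: Fixed set of relatedness classes used for per-class reporting.
PEDIGREE_CLASSES = frozenset(
    {
        "Factorial_parents",
        "MultiplePair_parents",
        "Factorial_progenies",
        "MultiplePair_progenies",
        "Unrelated",
    }
)

SITE_COLUMNS = ["chrom", "pos", "ref", "alts", "qual", "site_depth"]


@dataclass(frozen=True)
class VariantSite:
    """A single variant site.

    ``qual`` is the Phred-scaled calling quality (VCF QUAL column) and
    ``site_depth`` the read depth summed across samples. Sites may carry one
    or two alternative alleles: mapping against another species' reference
    means two alternative alleles and no reference allele can legitimately
    segregate, so triallelic sites are kept.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float = 0.0
    site_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alts)
        if not 2 <= n_alleles <= 3:
            raise ValueError(f"total allele count must be 2 or 3, got {n_alleles}")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if self.site_depth < 0:
            raise ValueError("site_depth must be >= 0")


def _check_sites_frame(sites: pd.DataFrame) -> pd.DataFrame:
    sites = sites.reset_index(drop=True)
    for col in ("chrom", "pos"):
        if col not in sites.columns:
            raise ValueError(f"sites frame lacks required column {col!r}")
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        raise ValueError("sites must be sorted by (chrom, pos)")
    if sites.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) in sites")
    return sites


@dataclass
class GenotypeMatrix:
    """Samples × sites allelic dosages with marker coordinates.

    ``dosage`` holds integers in {0, 1, 2, MISSING}. ``sites`` is a DataFrame
    with columns chrom, pos, ref, alts (comma-joined string), qual,
    site_depth. ``depth`` optionally carries per-sample × per-site read depth
    and ``sample_depth`` the per-sample mean coverage (X). ``alleles``
    optionally carries per-cell allele-code pairs (0 = ref, 1/2 = alts,
    MISSING) so multi-allelic genotypes keep allele identity.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    phased: bool = False
    sample_depth: np.ndarray | None = None
    depth: np.ndarray | None = None
    alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = _check_sites_frame(self.sites)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage")
            if self.sample_depth is None:
                self.sample_depth = self.depth.mean(axis=1)
        if self.alleles is not None:
            self.alleles = np.asarray(self.alleles, dtype=np.int8)
            if self.alleles.shape != (*self.dosage.shape, 2):
                raise ValueError("alleles shape must be samples x sites x 2")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        alts = tuple(a for a in str(row.get("alts", "A")).split(",") if a)
        return VariantSite(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row.get("ref", "N")),
            alts=alts or ("A",),
            qual=float(row.get("qual", 0.0)),
            site_depth=float(row.get("site_depth", 0.0)),
        )

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            sites=self.sites,
            dosage=self.dosage[idx],
            phased=self.phased,
            sample_depth=None if self.sample_depth is None else self.sample_depth[idx],
            depth=None if self.depth is None else self.depth[idx],
            alleles=None if self.alleles is None else self.alleles[idx],
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            phased=self.phased,
            sample_depth=self.sample_depth,
            depth=None if self.depth is None else self.depth[:, idx],
            alleles=None if self.alleles is None else self.alleles[:, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            dosage=self.dosage.copy(),
            phased=self.phased,
            sample_depth=None if self.sample_depth is None else self.sample_depth.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            alleles=None if self.alleles is None else self.alleles.copy(),
        )

    def site_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])


@dataclass
class HaplotypeSet:
    """Two 0/1 haplotypes per sample per site (phased, biallelic)."""

    samples: list[str]
    sites: pd.DataFrame
    hap: np.ndarray  # samples x 2 x sites, uint8

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = _check_sites_frame(self.sites)
        self.hap = np.asarray(self.hap, dtype=np.uint8)
        if self.hap.shape != (len(self.samples), 2, len(self.sites)):
            raise ValueError(
                f"hap shape {self.hap.shape} must be samples x 2 x sites"
            )
        if self.hap.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def dosage(self) -> np.ndarray:
        return self.hap.sum(axis=1).astype(np.int8)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            samples=self.samples, sites=self.sites, dosage=self.dosage(), phased=True
        )

    def take_samples(self, ids: list[str]) -> "HaplotypeSet":
        idx = [self.samples.index(s) for s in ids]
        return HaplotypeSet(samples=list(ids), sites=self.sites, hap=self.hap[idx])

    def take_sites(self, idx: np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(
            samples=self.samples,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            hap=self.hap[:, :, idx],
        )


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    klass: str


@dataclass
class Pedigree:
    """Individual / sire / dam records with a relatedness-class label.

    Classes follow the study's five levels of relatedness: parents and
    progenies of the factorial and the multiple-pair mating sets, plus
    unrelated accessions.
    """

    records: list[PedigreeRecord]
    _by_id: dict[str, PedigreeRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.klass not in PEDIGREE_CLASSES:
                raise ValueError(f"unknown pedigree class {rec.klass!r} for {rec.id}")
            if rec.id in self._by_id:
                raise ValueError(f"duplicate pedigree id {rec.id}")
            self._by_id[rec.id] = rec
        for rec in self.records:
            for par in (rec.sire, rec.dam):
                if par is not None and par not in self._by_id:
                    raise ValueError(f"parent {par!r} of {rec.id} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise ValueError(f"cyclic ancestry involving {iid}")
            state[iid] = 0
            rec = self._by_id[iid]
            for par in (rec.sire, rec.dam):
                if par is not None:
                    visit(par, stack + [iid])
            state[iid] = 1

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10000 + len(self.records)))
        try:
            for rec in self.records:
                visit(rec.id, [])
        finally:
            sys.setrecursionlimit(old)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, iid: str) -> PedigreeRecord:
        return self._by_id[iid]

    def klass(self, iid: str) -> str:
        return self._by_id[iid].klass

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        rec = self._by_id[iid]
        return rec.sire, rec.dam

    def offspring_of(self, iid: str) -> list[str]:
        return [r.id for r in self.records if iid in (r.sire, r.dam)]

    def grandparents_of(self, iid: str) -> list[str]:
        out: list[str] = []
        for par in self.parents_of(iid):
            if par is not None:
                out.extend(p for p in self.parents_of(par) if p is not None)
        return out

    def founders(self) -> list[str]:
        return [r.id for r in self.records if r.sire is None and r.dam is None]

    def topological_order(self) -> list[str]:
        """Parents before children."""
        done: set[str] = set()
        order: list[str] = []
        pending = list(self.records)
        while pending:
            progressed = False
            rest = []
            for rec in pending:
                parents_done = all(
                    p is None or p in done for p in (rec.sire, rec.dam)
                )
                if parents_done:
                    done.add(rec.id)
                    order.append(rec.id)
                    progressed = True
                else:
                    rest.append(rec)
            if not progressed:  # pragma: no cover - acyclicity already enforced
                raise ValueError("pedigree is not acyclic")
            pending = rest
        return order

    def trios(self, available: set[str] | None = None) -> list[tuple[str, str | None, str | None]]:
        """(child, sire, dam) tuples with at least one parent available.

        ``available`` restricts the individuals considered present (e.g. the
        samples of a genotype matrix); parents outside it are treated as
        unavailable, yielding duos or dropping the trio entirely.
        """
        out = []
        for rec in self.records:
            sire, dam = rec.sire, rec.dam
            if available is not None:
                if rec.id not in available:
                    continue
                sire = sire if sire in available else None
                dam = dam if dam in available else None
            if sire is not None or dam is not None:
                out.append((rec.id, sire, dam))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire or "" for r in self.records],
                "dam": [r.dam or "" for r in self.records],
                "class": [r.klass for r in self.records],
            }
        )


def genotype_matrix_from_arrays(
    chrom: np.ndarray,
    pos: np.ndarray,
    dosage: np.ndarray,
    samples: list[str] | None = None,
    **kwargs,
) -> GenotypeMatrix:
    """Convenience constructor used heavily in tests."""
    dosage = np.asarray(dosage)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": kwargs.pop("ref", ["A"] * n_sites),
            "alts": kwargs.pop("alts", ["T"] * n_sites),
            "qual": kwargs.pop("qual", np.zeros(n_sites)),
            "site_depth": kwargs.pop("site_depth", np.zeros(n_sites)),
        }
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, **kwargs)
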