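"""Pedigreed, phased, two-density synthetic genotype panels.

The generator emulates a poplar breeding study design: an almost-complete
factorial mating set (4 females x 4 males, 413 progenies in 14 full-sib
families), a multiple-pair mating set (8 females x 7 males, 598 progenies in
21 families, two of the females being themselves factorial progenies), six
unrelated accessions from wild populations and one grandparent — 1039
individuals in total, of which a 43-strong nodal subset is "sequenced" and
serves as the imputation reference.

Founder haplotypes carry tunable, monotonically decaying linkage
disequilibrium from a first-order Markov copying process; genotypes descend
through the pedigree by gene dropping with Haldane (Poisson, no interference)
recombination, so offspring are Mendelian-consistent by construction and the
data are phased by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    Pedigree,
    PedigreeRecord,
)

# ---------------------------------------------------------------------------
# Mating design


@dataclass(frozen=True)
class Cross:
    female: str
    male: str
    n_progeny: int


@dataclass
class StudyDesign:
    """Family structure: factorial crosses, multiple-pair crosses, unrelated.

    ``dual_role_females`` maps multiple-pair female ids onto factorial
    crosses: those females are themselves progenies of the named factorial
    cross (index into ``factorial_crosses``), reproducing individuals that are
    progeny in one mating set and parent in the other.
    """

    factorial_females: list[str]
    factorial_males: list[str]
    factorial_crosses: list[Cross]
    multipair_females: list[str]
    multipair_males: list[str]
    multipair_crosses: list[Cross]
    dual_role_females: dict[str, int] = field(default_factory=dict)
    n_unrelated: int = 6
    grandparent_of: str | None = None  # factorial parent with a known sire
    n_sequenced_progenies: int = 13


def default_design() -> StudyDesign:
    """The study-shaped design: 1039 individuals, 35 families, 23 parents."""
    ff = [f"FF{i}" for i in range(1, 5)]
    fm = [f"FM{i}" for i in range(1, 5)]
    # 14 of the 16 factorial combinations, 413 progenies
    combos = [(f, m) for f in ff for m in fm]
    combos = [c for c in combos if c not in {("FF4", "FM4"), ("FF3", "FM4")}]
    sizes = [30] * 7 + [29] * 7  # sums to 413
    factorial_crosses = [
        Cross(f, m, n) for (f, m), n in zip(combos, sizes)
    ]
    # two multiple-pair females are factorial progenies (dual role)
    dual = {"FP01_001": 0, "FP02_001": 1}
    mf = ["FP01_001", "FP02_001"] + [f"MF{i}" for i in range(3, 9)]
    mm = [f"MM{i}" for i in range(1, 8)]
    # 21 crosses, each parent in 1-5 crosses, 598 progenies
    pairs: list[tuple[str, str]] = []
    for i in range(5):
        for k in range(3):
            pairs.append((mf[i], mm[(i + k) % 7]))
    for i in range(5, 8):
        pairs.append((mf[i], mm[i % 7]))
        pairs.append((mf[i], mm[(i + 3) % 7]))
    sizes = [29] * 10 + [28] * 11  # sums to 598
    multipair_crosses = [Cross(f, m, n) for (f, m), n in zip(pairs, sizes)]
    return StudyDesign(
        factorial_females=ff,
        factorial_males=fm,
        factorial_crosses=factorial_crosses,
        multipair_females=mf,
        multipair_males=mm,
        multipair_crosses=multipair_crosses,
        dual_role_females=dual,
        n_unrelated=6,
        grandparent_of="FF1",
    )


def build_pedigree(design: StudyDesign) -> Pedigree:
    """Materialise a StudyDesign into a Pedigree with class labels."""
    records: list[PedigreeRecord] = []
    known = set()

    def add(iid, sire, dam, klass):
        records.append(PedigreeRecord(id=iid, sire=sire, dam=dam, klass=klass))
        known.add(iid)

    if design.grandparent_of is not None:
        add("GP1", None, None, "Factorial_parents")
    for f in design.factorial_females + design.factorial_males:
        sire = "GP1" if f == design.grandparent_of else None
        add(f, sire, None, "Factorial_parents")
    progeny_names: dict[int, list[str]] = {}
    for ci, cross in enumerate(design.factorial_crosses):
        if cross.male not in known or cross.female not in known:
            raise ValueError(
                f"factorial cross {cross.female} x {cross.male} names an unknown parent"
            )
        names = [f"FP{ci + 1:02d}_{k + 1:03d}" for k in range(cross.n_progeny)]
        progeny_names[ci] = names
        for name in names:
            add(name, cross.male, cross.female, "Factorial_progenies")
    for f in design.multipair_females:
        if f in design.dual_role_females:
            ci = design.dual_role_females[f]
            if f not in progeny_names.get(ci, []):
                raise ValueError(
                    f"dual-role female {f} is not a progeny of factorial cross {ci}"
                )
            continue  # already added as a factorial progeny
        add(f, None, None, "MultiplePair_parents")
    for m in design.multipair_males:
        add(m, None, None, "MultiplePair_parents")
    for ci, cross in enumerate(design.multipair_crosses):
        if cross.male not in known or cross.female not in known:
            raise ValueError(
                f"multiple-pair cross {cross.female} x {cross.male} names an "
                "unknown parent"
            )
        for k in range(cross.n_progeny):
            add(f"MP{ci + 1:02d}_{k + 1:03d}", cross.male, cross.female,
                "MultiplePair_progenies")
    for k in range(design.n_unrelated):
        add(f"U{k + 1}", None, None, "Unrelated")
    return Pedigree(records=records)


def reference_individuals(ped: Pedigree, design: StudyDesign) -> list[str]:
    """The sequenced nodal subset: grandparent, all parents, unrelated, and
    progenies chosen so every parent has at least one sequenced offspring."""
    ids: list[str] = []
    if design.grandparent_of is not None:
        ids.append("GP1")
    parents = list(
        dict.fromkeys(
            design.factorial_females
            + design.factorial_males
            + design.multipair_females
            + design.multipair_males
        )
    )
    ids.extend(parents)  # dual-role females are in multipair_females
    covered: set[str] = set()
    # dual-role females are sequenced parents and already cover the parents
    # of their factorial cross
    for f, ci in design.dual_role_females.items():
        cross = design.factorial_crosses[ci]
        covered.update((cross.female, cross.male))

    def progeny_name(ci: int, prefix: str) -> str:
        name = f"{prefix}{ci + 1:02d}_001"
        if name in design.dual_role_females:
            name = f"{prefix}{ci + 1:02d}_002"
        return name

    all_crosses = [
        (ci, cross, "FP") for ci, cross in enumerate(design.factorial_crosses)
    ] + [(ci, cross, "MP") for ci, cross in enumerate(design.multipair_crosses)]
    chosen: list[str] = []
    chosen_crosses: set[tuple[str, int]] = set()
    # greedy max-coverage: each sequenced progeny covers both its parents
    all_parents = {p for _, c, _ in all_crosses for p in (c.female, c.male)}
    while not covered >= all_parents:
        candidates = [
            (ci, c, prefix)
            for ci, c, prefix in all_crosses
            if (prefix, ci) not in chosen_crosses
        ]
        if not candidates:
            break
        ci, c, prefix = max(
            candidates, key=lambda t: (len({t[1].female, t[1].male} - covered), -t[0])
        )
        if not {c.female, c.male} - covered:
            break
        chosen.append(progeny_name(ci, prefix))
        chosen_crosses.add((prefix, ci))
        covered.update((c.female, c.male))
    # pad with additional progenies up to the design's sequenced-progeny count
    for ci, c, prefix in all_crosses:
        if len(chosen) >= design.n_sequenced_progenies:
            break
        if (prefix, ci) not in chosen_crosses:
            chosen.append(progeny_name(ci, prefix))
            chosen_crosses.add((prefix, ci))
    ids.extend(chosen)
    ids.extend(f"U{k + 1}" for k in range(design.n_unrelated))
    return ids


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class DepthSpec:
    """Per-individual mean coverage: lognormal with mean ``mean`` (X),
    clipped to [low, high]; ``sigma = 0`` fixes every individual at ``mean``."""

    mean: float = 13.0
    low: float = 4.0
    high: float = 52.0
    sigma: float = 0.45


@dataclass
class SimConfig:
    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    n_seq_sites: int = 20_000  # per chromosome
    chip_fraction: float = 0.005
    founder_maf_beta: tuple[float, float] = (0.5, 0.5)
    ld_rho: float = 0.998
    recomb_rate: float = 2.0  # cM per Mb
    depth: DepthSpec = field(default_factory=DepthSpec)
    qual_shape: float = 4.0
    qual_scale: float = 15.0
    error_rate: float = 0.0
    missing_rate_chip: float = 0.01
    chip_maf_floor: float = 0.1
    chip_density_alpha: float | None = 2.0  # None -> even spacing
    design: StudyDesign = field(default_factory=default_design)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.chip_fraction < 1:
            raise ValueError("chip_fraction must be in (0,1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0,1)")
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")
        for name in ("n_chrom", "chrom_length_bp", "n_seq_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class FounderPool:
    """Founder haplotypes per chromosome plus the site table."""

    sites: pd.DataFrame  # chrom, pos (global, sorted)
    hap: np.ndarray  # n_haplotypes x n_total_sites, uint8
    freq: np.ndarray  # per-site founder alternative-allele frequency

    @property
    def n_haplotypes(self) -> int:
        return self.hap.shape[0]


# ---------------------------------------------------------------------------
# Founder haplotypes


def _site_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for c in range(cfg.n_chrom):
        pos = rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=cfg.n_seq_sites, replace=False
        )
        pos.sort()
        frames.append(pd.DataFrame({"chrom": f"chr{c + 1}", "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    sites["ref"] = "A"
    sites["alts"] = "T"
    sites["qual"] = 0.0
    sites["site_depth"] = 0.0
    return sites


def simulate_founder_haplotypes(
    cfg: SimConfig, n_haplotypes: int, rng: np.random.Generator | None = None
) -> FounderPool:
    """Founder pool with first-order Markov LD.

    Per site the alternative-allele frequency is Beta-distributed. Each
    haplotype is generated left-to-right through a latent uniform that, with
    probability ``ld_rho``, persists from the previous site (the allele then
    keeps its frequency rank) and is otherwise redrawn — inducing pairwise LD
    that decays geometrically with inter-site lag.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sites = _site_table(cfg, rng)
    m = len(sites)
    a, b = cfg.founder_maf_beta
    freq = rng.beta(a, b, size=m)
    freq = np.clip(freq, 1.0 / (2 * max(n_haplotypes, 2)), None)
    hap = np.empty((n_haplotypes, m), dtype=np.uint8)
    chrom_codes = pd.factorize(sites["chrom"])[0]
    fresh_u = rng.random((n_haplotypes, m))
    refresh = rng.random((n_haplotypes, m)) >= cfg.ld_rho
    # force a fresh draw at every chromosome start
    starts = np.r_[True, chrom_codes[1:] != chrom_codes[:-1]]
    refresh[:, starts] = True
    idx = np.where(refresh, np.arange(m)[None, :], 0)
    last = np.maximum.accumulate(idx, axis=1)
    u = np.take_along_axis(fresh_u, last, axis=1)
    hap[:] = (u < freq[None, :]).astype(np.uint8)
    return FounderPool(sites=sites, hap=hap, freq=freq)


# ---------------------------------------------------------------------------
# Gene dropping


def _chrom_slices(sites: pd.DataFrame) -> list[tuple[str, slice]]:
    out = []
    chroms = sites["chrom"].to_numpy()
    pos = 0
    for chrom in pd.unique(chroms):
        n = int((chroms == chrom).sum())
        out.append((str(chrom), slice(pos, pos + n)))
        pos += n
    return out


def _gamete(
    parent_hap: np.ndarray,  # 2 x n_sites (one chromosome)
    pos: np.ndarray,
    length_bp: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete: crossover count ~ Poisson(rate * Mb / 100),
    breakpoints uniform (Haldane, no interference)."""
    expected = recomb_rate * (length_bp / 1e6) / 100.0
    n_cross = rng.poisson(expected)
    start = rng.integers(0, 2)
    if n_cross == 0:
        return parent_hap[start].copy()
    breaks = np.sort(rng.integers(1, length_bp + 1, size=n_cross))
    seg = (start + np.searchsorted(breaks, pos, side="right")) % 2
    return np.where(seg == 0, parent_hap[0], parent_hap[1]).astype(np.uint8)


def gene_drop(
    ped: Pedigree,
    pool: FounderPool,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> HaplotypeSet:
    """Drop founder haplotypes down the pedigree with recombination.

    Founders (and the unknown side of half-founders) receive distinct pool
    haplotypes; each non-founder receives one recombinant gamete per parent,
    so every site is Mendelian-consistent by construction. Haplotype 0 is
    paternal, haplotype 1 maternal where parents are known.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    order = ped.topological_order()
    founders = ped.founders()
    n_unknown_sides = sum(
        (ped.record(i).sire is None) ^ (ped.record(i).dam is None) for i in ped.ids()
    )
    need = 2 * len(founders) + n_unknown_sides
    if need > pool.n_haplotypes:
        raise ValueError(
            f"pedigree needs {need} founder haplotypes, pool has {pool.n_haplotypes}"
        )
    sites = pool.sites
    m = len(sites)
    chrom_sl = _chrom_slices(sites)
    pos_all = sites["pos"].to_numpy()
    hap = np.zeros((len(ped), 2, m), dtype=np.uint8)
    index = {iid: k for k, iid in enumerate(ped.ids())}
    next_pool = 0

    def fresh_hap() -> np.ndarray:
        nonlocal next_pool
        h = pool.hap[next_pool]
        next_pool += 1
        return h

    for iid in order:
        k = index[iid]
        sire, dam = ped.parents_of(iid)
        for side, parent in enumerate((sire, dam)):
            if parent is None:
                hap[k, side] = fresh_hap()
            else:
                pk = index[parent]
                for chrom, sl in chrom_sl:
                    hap[k, side, sl] = _gamete(
                        hap[pk, :, sl],
                        pos_all[sl],
                        cfg.chrom_length_bp,
                        cfg.recomb_rate,
                        rng,
                    )
    return HaplotypeSet(samples=ped.ids(), sites=sites, hap=hap)


# ---------------------------------------------------------------------------
# Chip selection, depth/quality, error models


def select_chip_subset(
    hs: HaplotypeSet,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, np.ndarray]:
    """Pick chip sites from the sequence panel; return (chip, seq, chip_idx).

    Stratified selection: the chromosome is cut into equal-width bins (one
    per chip marker on average) and the highest-MAF site with MAF >=
    ``chip_maf_floor`` in each bin is taken, emulating a chip enriched in
    high-MAF markers. With ``chip_density_alpha`` set, per-bin marker counts
    are Dirichlet-multinomial distributed instead of one-per-bin, emulating
    the heterogeneous marker density of real array designs.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    dosage = hs.dosage()
    n2 = 2 * hs.n_samples
    p = dosage.astype(np.int64).sum(axis=0) / n2
    maf = np.minimum(p, 1 - p)
    eligible = maf >= cfg.chip_maf_floor
    chip_idx: list[int] = []
    for chrom, sl in _chrom_slices(hs.sites):
        pos = hs.sites["pos"].to_numpy()[sl]
        n_sites = sl.stop - sl.start
        n_chip = max(1, int(round(cfg.chip_fraction * n_sites)))
        n_elig = int(eligible[sl].sum())
        if n_elig < n_chip:
            raise ValueError(
                f"{chrom}: only {n_elig} sites with MAF >= {cfg.chip_maf_floor}, "
                f"need {n_chip} (shortfall {n_chip - n_elig})"
            )
        edges = np.linspace(0, cfg.chrom_length_bp, n_chip + 1)
        bin_of = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_chip - 1)
        if cfg.chip_density_alpha is None:
            counts = np.ones(n_chip, dtype=np.int64)
        else:
            w = rng.dirichlet(np.full(n_chip, cfg.chip_density_alpha))
            counts = rng.multinomial(n_chip, w)
        taken = 0
        for b in range(n_chip):
            want = int(counts[b])
            if want == 0:
                continue
            in_bin = np.flatnonzero((bin_of == b) & eligible[sl])
            if in_bin.size == 0:
                continue
            top = in_bin[np.argsort(maf[sl][in_bin])[::-1][:want]]
            chip_idx.extend(sl.start + np.sort(top))
            taken += len(top)
        # top up from remaining eligible sites if heterogeneity left a deficit
        if taken < n_chip:
            pool_idx = np.flatnonzero(eligible[sl]) + sl.start
            pool_idx = np.setdiff1d(pool_idx, np.array(chip_idx, dtype=np.int64))
            extra = pool_idx[np.argsort(maf[pool_idx])[::-1][: n_chip - taken]]
            chip_idx.extend(extra)
    chip_idx_arr = np.array(sorted(chip_idx), dtype=np.int64)
    seq_gm = hs.to_genotype_matrix()
    chip_gm = seq_gm.take_sites(chip_idx_arr)
    return chip_gm, seq_gm, chip_idx_arr


def simulate_depth_qual(
    gm: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    missing_at_zero_depth: bool = False,
) -> GenotypeMatrix:
    """Fill per-cell depth, per-sample mean depth, site depth and QUAL.

    Individual mean depths come from the clipped lognormal of
    :class:`DepthSpec`; per-cell depths are Poisson around the individual
    mean; QUAL is Gamma-distributed with a floor at 0.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    out = gm.copy()
    d = cfg.depth
    if d.sigma <= 0:
        means = np.full(gm.n_samples, d.mean)
    else:
        mu = np.log(d.mean) - d.sigma**2 / 2.0
        means = np.clip(rng.lognormal(mu, d.sigma, size=gm.n_samples), d.low, d.high)
    depth = rng.poisson(means[:, None], size=(gm.n_samples, gm.n_sites))
    out.depth = depth.astype(np.int32)
    out.sample_depth = depth.mean(axis=1)
    out.sites = out.sites.copy()
    out.sites["site_depth"] = depth.sum(axis=0).astype(float)
    out.sites["qual"] = rng.gamma(cfg.qual_shape, cfg.qual_scale, size=gm.n_sites)
    if missing_at_zero_depth:
        out.dosage = np.where(depth == 0, MISSING, out.dosage).astype(np.int8)
    return out


def add_genotype_errors(
    gm: GenotypeMatrix,
    error_rate: float,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Flip non-missing dosages to a different value with probability
    ``error_rate`` and independently mask cells MISSING at ``missing_rate``."""
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = gm.copy()
    dos = out.dosage
    called = dos != MISSING
    if error_rate > 0:
        flip = called & (rng.random(dos.shape) < error_rate)
        # move to one of the two other dosage values uniformly
        shift = rng.integers(1, 3, size=dos.shape)
        dos = np.where(flip, (dos + shift) % 3, dos).astype(np.int8)
    if missing_rate > 0:
        mask = called & (rng.random(dos.shape) < missing_rate)
        dos = np.where(mask, MISSING, dos).astype(np.int8)
    out.dosage = dos
    out.phased = False if (error_rate > 0 or missing_rate > 0) else out.phased
    return out


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SimulatedStudy:
    """Everything the downstream stages consume, at reference scale."""

    config: SimConfig
    pedigree: Pedigree
    reference_ids: list[str]
    haps_ref: HaplotypeSet  # phased truth, reference individuals, seq density
    seq_ref: GenotypeMatrix  # truth dosages + depth/qual, reference individuals
    chip_all: GenotypeMatrix  # chip panel for the whole population (with errors)
    chip_truth_all: GenotypeMatrix  # chip panel before error/missing injection
    chip_idx: np.ndarray  # chip site indices into the sequence site table


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run the full generator under one seed: pedigree, gene drop, chip
    selection, depth/qual simulation and chip error/missingness injection."""
    rng = np.random.default_rng(cfg.seed)
    ped = build_pedigree(cfg.design)
    founders = ped.founders()
    n_unknown = sum(
        (ped.record(i).sire is None) ^ (ped.record(i).dam is None) for i in ped.ids()
    )
    pool = simulate_founder_haplotypes(
        cfg, n_haplotypes=2 * len(founders) + n_unknown, rng=rng
    )
    haps_all = gene_drop(ped, pool, cfg, rng=rng)
    chip_truth_all, _, chip_idx = select_chip_subset(haps_all, cfg, rng=rng)
    ref_ids = reference_individuals(ped, cfg.design)
    haps_ref = haps_all.take_samples(ref_ids)
    seq_ref = haps_ref.to_genotype_matrix()
    seq_ref = simulate_depth_qual(seq_ref, cfg, rng=rng)
    chip_all = add_genotype_errors(
        chip_truth_all,
        error_rate=cfg.error_rate,
        missing_rate=cfg.missing_rate_chip,
        rng=rng,
    )
    return SimulatedStudy(
        config=cfg,
        pedigree=ped,
        reference_ids=ref_ids,
        haps_ref=haps_ref,
        seq_ref=seq_ref,
        chip_all=chip_all,
        chip_truth_all=chip_truth_all,
        chip_idx=chip_idx,
    )
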