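"""Imputers: frequency random-fill lower bound and a windowed family/LD imputer.

Both are scikit-learn-style estimators (``fit`` on a phased reference panel,
``transform`` a chip-density target panel) so they compose with sklearn
tooling; :func:`frequency_fill_impute` and :func:`family_ld_impute` are thin
functional wrappers over them.

The family/LD imputer is a documented stand-in for pedigree+LD imputation
software of the FImpute family, not a reimplementation of any unpublished
algorithm: it scans each chromosome with shrinking rolling windows of chip
markers, matches target haplotypes against the reference haplotype library —
relatives first — and copies matching reference haplotypes at all sequence
sites a window spans, falling back to allele-frequency fill where no match
exists.
"""

from __future__ import annotations

import subprocess
import sys
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import MISSING, GenotypeMatrix, HaplotypeSet, Pedigree
from .filtering import _TRIO_OK

# provenance codes
PROV_OBSERVED = 0
PROV_PEDIGREE = 1
PROV_HAPLOTYPE = 2
PROV_FREQUENCY = 3
PROVENANCE_LABELS = {
    PROV_OBSERVED: "observed",
    PROV_PEDIGREE: "pedigree_deduced",
    PROV_HAPLOTYPE: "haplotype_copied",
    PROV_FREQUENCY: "frequency_filled",
}


@dataclass
class ImputationTask:
    """Reference panel (phased, sequence density), chip-density target and
    pedigree. Every target site must exist in the reference by (chrom, pos)."""

    reference: HaplotypeSet
    target: GenotypeMatrix
    pedigree: Pedigree | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        idx = target_site_indices(self.reference, self.target)
        if (idx < 0).any():
            missing = self.target.sites.iloc[np.flatnonzero(idx < 0)]
            raise ValueError(
                f"{(idx < 0).sum()} target sites absent from reference, first: "
                f"{missing.iloc[0]['chrom']}:{missing.iloc[0]['pos']}"
            )


@dataclass
class ImputationResult:
    """Imputed genotypes at sequence density plus per-cell provenance."""

    imputed: GenotypeMatrix
    provenance: np.ndarray  # samples x sites, uint8 provenance codes
    haplotypes: HaplotypeSet | None = None


def target_site_indices(reference, target: GenotypeMatrix) -> np.ndarray:
    """Indices of the target's sites within the reference site table (-1 when
    absent). ``reference`` may be a panel object or a bare sites DataFrame."""
    ref_sites = reference if isinstance(reference, pd.DataFrame) else reference.sites
    ref_keys = pd.MultiIndex.from_frame(ref_sites[["chrom", "pos"]])
    tgt_keys = pd.MultiIndex.from_frame(target.sites[["chrom", "pos"]])
    return ref_keys.get_indexer(tgt_keys)


def _chrom_slices(sites: pd.DataFrame) -> list[slice]:
    chroms = sites["chrom"].to_numpy()
    out, start = [], 0
    for chrom in pd.unique(chroms):
        n = int((chroms == chrom).sum())
        out.append(slice(start, start + n))
        start += n
    return out


class FrequencyFillImputer(TransformerMixin, BaseEstimator):
    """Allelic-frequency random fill: the imputation-accuracy lower bound.

    Every non-chip allele is drawn Bernoulli(p_alt) from the reference
    panel's alternative-allele frequency (``mode="allele"``), or the whole
    genotype is drawn from the reference genotype frequencies
    (``mode="genotype"``). Chip sites pass through unchanged.
    """

    def __init__(self, mode: str = "allele", random_state: int | None = 0):
        self.mode = mode
        self.random_state = random_state

    def fit(self, reference: HaplotypeSet | GenotypeMatrix, pedigree=None):
        if self.mode not in ("allele", "genotype"):
            raise ValueError("mode must be 'allele' or 'genotype'")
        dosage = (
            reference.dosage() if isinstance(reference, HaplotypeSet)
            else reference.dosage
        )
        called = dosage != MISSING
        n_called = np.maximum(called.sum(axis=0), 1)
        self.p_alt_ = (dosage * called).sum(axis=0) / (2.0 * n_called)
        self.genotype_freq_ = np.stack(
            [((dosage == g) & called).sum(axis=0) / n_called for g in (0, 1, 2)]
        )
        self.sites_ = reference.sites
        return self

    def transform(self, target: GenotypeMatrix) -> ImputationResult:
        idx = target_site_indices(self.sites_, target)
        if (idx < 0).any():
            raise ValueError("target sites must be a subset of reference sites")
        rng = np.random.default_rng(self.random_state)
        n, m = target.n_samples, len(self.sites_)
        if self.mode == "allele":
            hap = (rng.random((n, 2, m)) < self.p_alt_[None, None, :]).astype(np.uint8)
            dosage = hap.sum(axis=1).astype(np.int8)
        else:
            u = rng.random((n, m))
            cum = np.cumsum(self.genotype_freq_, axis=0)
            dosage = (u[None, :, :] >= cum[:, None, :]).sum(axis=0).astype(np.int8)
            hap = None
        prov = np.full((n, m), PROV_FREQUENCY, dtype=np.uint8)
        observed = target.dosage != MISSING
        dosage[:, idx] = np.where(observed, target.dosage, dosage[:, idx])
        prov[:, idx] = np.where(observed, PROV_OBSERVED, PROV_FREQUENCY)
        gm = GenotypeMatrix(
            samples=target.samples, sites=self.sites_, dosage=dosage, phased=False
        )
        haps = None
        if hap is not None:
            # make chip-site haplotypes consistent with pass-through dosages
            hap[:, 0, idx] = np.where(observed, (target.dosage >= 1), hap[:, 0, idx])
            hap[:, 1, idx] = np.where(observed, (target.dosage == 2), hap[:, 1, idx])
            haps = HaplotypeSet(samples=target.samples, sites=self.sites_, hap=hap)
        return ImputationResult(imputed=gm, provenance=prov, haplotypes=haps)


class FamilyLDImputer(TransformerMixin, BaseEstimator):
    """Windowed haplotype-library matching with pedigree priority.

    Per chromosome: (1) target chip genotypes are phased where possible by
    Mendelian deduction from reference parents; (2) rolling windows of W chip
    markers (largest W first, advancing by ``W * (1 - overlap)``) search the
    reference library for diplotypes — pairs of reference haplotypes whose
    allele sum matches the observed chip dosage at every called window site
    and that satisfy the phase-deduced constraints (an unphased heterozygous
    site thereby has both phase configurations tried) — searching relatives
    first (the transmitting parent, the other parent, grandparents,
    offspring, then the whole panel); matching haplotypes vote on every
    sequence site the window spans; (3) votes are combined by majority, ties
    resolved by the smallest-window majority, then by the relative-priority
    vote; (4) cells never covered fall through to frequency fill.
    """

    def __init__(
        self,
        window_sizes: tuple[int, ...] = (64, 16, 4),
        overlap: float = 0.5,
        random_state: int | None = 0,
    ):
        self.window_sizes = window_sizes
        self.overlap = overlap
        self.random_state = random_state

    def fit(self, reference: HaplotypeSet, pedigree: Pedigree | None = None):
        if not isinstance(reference, HaplotypeSet):
            raise TypeError("FamilyLDImputer requires a phased HaplotypeSet reference")
        if sorted(self.window_sizes, reverse=True) != list(self.window_sizes):
            raise ValueError("window_sizes must be in descending order")
        self.reference_ = reference
        self.pedigree_ = pedigree
        self.sites_ = reference.sites
        n = reference.n_samples
        self.hap_lib_ = reference.hap.reshape(2 * n, reference.n_sites)
        self.hap_owner_ = {s: (2 * i, 2 * i + 1) for i, s in enumerate(reference.samples)}
        dosage = reference.dosage()
        self.p_alt_ = dosage.sum(axis=0) / (2.0 * n)
        self.ref_dosage_ = dosage
        return self

    # -- helpers ------------------------------------------------------------

    def _relative_tiers(self, sample_id: str, hap_i: int) -> list[np.ndarray]:
        """Candidate haplotype rows, nearest relatives first.

        Haplotype 0 is paternal and 1 maternal, so the transmitting parent's
        haplotypes are searched before the other parent's, then grandparents,
        then offspring (informative for parental targets), then the panel.
        """
        owner = self.hap_owner_
        tiers: list[np.ndarray] = []
        seen: set[int] = set()

        def add(ids: list[str | None]) -> None:
            rows = [
                r for i in ids if i is not None and i in owner
                for r in owner[i] if r not in seen
            ]
            if rows:
                seen.update(rows)
                tiers.append(np.array(rows, dtype=np.int64))

        ped = self.pedigree_
        if ped is not None and sample_id in ped:
            sire, dam = ped.parents_of(sample_id)
            own, other = (sire, dam) if hap_i == 0 else (dam, sire)
            add([own])
            add([other])
            add(ped.grandparents_of(sample_id))
            add(ped.offspring_of(sample_id))
        rest = np.array(
            [r for r in range(self.hap_lib_.shape[0]) if r not in seen],
            dtype=np.int64,
        )
        if rest.size:
            tiers.append(rest)
        # cumulative: level i searches everything at least as close as tier i
        cum: list[np.ndarray] = []
        for tier in tiers:
            cum.append(np.concatenate([cum[-1], tier]) if cum else tier)
        return cum

    def _phase_target(self, sample_id: str, chip_dos: np.ndarray,
                      chip_idx: np.ndarray) -> np.ndarray:
        """Phase chip genotypes into 2 x n_chip alleles; -1 where unknown.

        Haplotype 0 is paternal. Heterozygous sites resolve only when a
        reference parent is homozygous there; the rest stay ambiguous and act
        as wildcards during matching (both phase configurations can match).
        """
        n_chip = chip_dos.shape[0]
        t = np.full((2, n_chip), -1, dtype=np.int8)
        hom = chip_dos == 0
        t[:, hom] = 0
        hom2 = chip_dos == 2
        t[:, hom2] = 1
        het = chip_dos == 1
        ped = self.pedigree_
        if ped is not None and sample_id in ped and het.any():
            sire, dam = ped.parents_of(sample_id)
            ref_samples = set(self.hap_owner_)
            sire_dos = dam_dos = None
            if sire in ref_samples:
                sire_dos = self.ref_dosage_[
                    list(self.hap_owner_).index(sire)
                ][chip_idx]
            if dam in ref_samples:
                dam_dos = self.ref_dosage_[
                    list(self.hap_owner_).index(dam)
                ][chip_idx]
            if sire_dos is not None:
                fix = het & (sire_dos != 1) & (sire_dos != MISSING)
                t[0, fix] = (sire_dos[fix] // 2).astype(np.int8)
                t[1, fix] = 1 - t[0, fix]
            if dam_dos is not None:
                fix = het & (dam_dos != 1) & (dam_dos != MISSING) & (t[0] == -1)
                t[1, fix] = (dam_dos[fix] // 2).astype(np.int8)
                t[0, fix] = 1 - t[1, fix]
        return t

    def _windows(self, n_chip: int) -> list[tuple[int, int, int]]:
        """(level, start, stop) chip-marker windows, largest W first."""
        out = []
        for level, w in enumerate(self.window_sizes):
            w_eff = min(w, n_chip)
            step = max(1, int(round(w_eff * (1 - self.overlap))))
            starts = list(range(0, n_chip - w_eff + 1, step))
            if starts[-1] != n_chip - w_eff:
                starts.append(n_chip - w_eff)
            out.extend((level, s, s + w_eff) for s in starts)
        return out

    # -- main ---------------------------------------------------------------

    def transform(self, target: GenotypeMatrix) -> ImputationResult:
        lib = self.hap_lib_
        m = lib.shape[1]
        chip_idx_all = target_site_indices(self.reference_, target)
        if (chip_idx_all < 0).any():
            raise ValueError("target sites must be a subset of reference sites")
        rng = np.random.default_rng(self.random_state)
        n_levels = len(self.window_sizes)
        n_tgt = target.n_samples
        out_hap = np.zeros((n_tgt, 2, m), dtype=np.uint8)
        prov = np.full((n_tgt, m), PROV_FREQUENCY, dtype=np.uint8)
        chrom_sl_ref = _chrom_slices(self.sites_)
        tgt_chrom = target.sites["chrom"].to_numpy()

        for si, sample_id in enumerate(target.samples):
            chip_dos = target.dosage[si]
            t_all = self._phase_target(sample_id, chip_dos, chip_idx_all)
            tiers_by_hap = [
                self._relative_tiers(sample_id, h) for h in range(2)
            ]
            covered = np.zeros((2, m), dtype=bool)
            votes = np.zeros((2, n_levels, 2, m), dtype=np.int16)  # hap,lvl,allele
            rel_votes = np.zeros((2, 2, m), dtype=np.int16)
            n_tiers = max(len(t) for t in tiers_by_hap)
            for sl in chrom_sl_ref:
                chrom = self.sites_["chrom"].iloc[sl.start]
                in_c = np.flatnonzero(tgt_chrom == chrom)
                if in_c.size == 0:
                    continue
                cidx = chip_idx_all[in_c]  # ref-site indices of chrom chip markers
                lib_c = lib[:, cidx]  # haplotype library at the chrom's chip sites
                dos_c = chip_dos[in_c].astype(np.int8)
                for level, w0, w1 in self._windows(in_c.size):
                    cols = cidx[w0:w1]
                    # terminal windows extend to the chromosome edges so the
                    # sequence beyond the outermost chip markers is covered
                    span_lo = sl.start if w0 == 0 else cols[0]
                    span_hi = sl.stop if w1 == in_c.size else cols[-1] + 1
                    span = slice(span_lo, span_hi)
                    dos_w = dos_c[w0:w1]
                    dos_known = dos_w != MISSING
                    if not dos_known.any():
                        continue
                    t0 = t_all[0, in_c[w0:w1]]
                    t1 = t_all[1, in_c[w0:w1]]
                    a_set = b_set = None
                    first_tier = False
                    for ti in range(n_tiers):
                        ta = tiers_by_hap[0][min(ti, len(tiers_by_hap[0]) - 1)]
                        tb = tiers_by_hap[1][min(ti, len(tiers_by_hap[1]) - 1)]
                        la = lib_c[ta][:, w0:w1]
                        lb = lib_c[tb][:, w0:w1]
                        # phase-deduced constraints on each side
                        ok_a = ((la == t0) | (t0 < 0)).all(axis=1)
                        ok_b = ((lb == t1) | (t1 < 0)).all(axis=1)
                        if not ok_a.any() or not ok_b.any():
                            continue
                        la_v = la[ok_a]
                        lb_v = lb[ok_b]
                        # diplotype consistency: paired alleles must sum to
                        # the observed dosage at every called chip site
                        req = dos_w[None, :] - la_v  # required partner allele
                        feasible = (((req == 0) | (req == 1)) | ~dos_known).all(axis=1)
                        if not feasible.any():
                            continue
                        req = req[feasible]
                        pair_ok = (
                            (lb_v[None, :, :] == req[:, None, :]) | ~dos_known
                        ).all(axis=2)  # a x b
                        if not pair_ok.any():
                            continue
                        a_rows = ta[ok_a][feasible][pair_ok.any(axis=1)]
                        b_rows = tb[ok_b][pair_ok.any(axis=0)]
                        a_set, b_set = a_rows, b_rows
                        first_tier = ti == 0 and n_tiers > 1
                        break
                    if a_set is None:
                        continue
                    for hap_i, rows in ((0, a_set), (1, b_set)):
                        frac = lib[rows, span].mean(axis=0)
                        # an exactly split window is ambiguous and abstains
                        vote1 = frac > 0.5
                        vote0 = frac < 0.5
                        votes[hap_i, level, 1, span] += vote1
                        votes[hap_i, level, 0, span] += vote0
                        if first_tier:
                            rel_votes[hap_i, 1, span] += vote1
                            rel_votes[hap_i, 0, span] += vote0
                        covered[hap_i, span] |= vote1 | vote0
            # combine votes: overall majority; ties -> smallest-W majority;
            # ties -> relative vote; ties -> frequency rounding
            tot = votes.sum(axis=1)  # hap, allele, site
            allele = np.where(tot[:, 1] > tot[:, 0], 1,
                              np.where(tot[:, 0] > tot[:, 1], 0, -1)).astype(np.int8)
            tie = allele == -1
            if tie.any():
                small = votes[:, -1]  # smallest window level
                allele = np.where(
                    tie & (small[:, 1] > small[:, 0]), 1,
                    np.where(tie & (small[:, 0] > small[:, 1]), 0, allele),
                ).astype(np.int8)
                tie = allele == -1
            if tie.any():
                allele = np.where(
                    tie & (rel_votes[:, 1] > rel_votes[:, 0]), 1,
                    np.where(tie & (rel_votes[:, 0] > rel_votes[:, 1]), 0, allele),
                ).astype(np.int8)
                tie = allele == -1
            if tie.any():
                allele = np.where(tie, (self.p_alt_[None, :] >= 0.5), allele
                                  ).astype(np.int8)
            fill = ~covered
            if fill.any():
                draws = (rng.random((2, m)) < self.p_alt_[None, :]).astype(np.int8)
                allele = np.where(fill, draws, allele)
            out_hap[si] = allele.astype(np.uint8)
            prov[si] = np.where(covered.all(axis=0), PROV_HAPLOTYPE, PROV_FREQUENCY)

        dosage = out_hap.sum(axis=1).astype(np.int8)
        # chip-site pass-through for observed genotypes
        observed = target.dosage != MISSING
        dosage[:, chip_idx_all] = np.where(observed, target.dosage,
                                           dosage[:, chip_idx_all])
        pcol = prov[:, chip_idx_all]
        prov[:, chip_idx_all] = np.where(observed, PROV_OBSERVED, pcol)
        out_hap[:, 0, chip_idx_all] = np.where(observed, target.dosage >= 1,
                                               out_hap[:, 0, chip_idx_all])
        out_hap[:, 1, chip_idx_all] = np.where(observed, target.dosage == 2,
                                               out_hap[:, 1, chip_idx_all])
        gm = GenotypeMatrix(samples=target.samples, sites=self.sites_,
                            dosage=dosage, phased=True)
        haps = HaplotypeSet(samples=target.samples, sites=self.sites_, hap=out_hap)
        return ImputationResult(imputed=gm, provenance=prov, haplotypes=haps)


# ---------------------------------------------------------------------------
# Chip missing-data pre-pass


def fill_chip_missing(
    chip: GenotypeMatrix, ped: Pedigree | None = None, seed: int = 0
) -> tuple[GenotypeMatrix, np.ndarray]:
    """First-round imputation of residual chip missingness.

    MISSING cells are filled by unambiguous Mendelian deduction from called
    parents and offspring where possible, otherwise by a within-chip
    allele-frequency draw. Returns the completed matrix and a provenance
    array (observed / pedigree_deduced / frequency_filled).
    """
    out = chip.copy()
    dos = out.dosage
    prov = np.full(dos.shape, PROV_OBSERVED, dtype=np.uint8)
    prov[dos == MISSING] = PROV_FREQUENCY
    if ped is not None:
        idx = {s: i for i, s in enumerate(out.samples)}
        sample_set = set(out.samples)
        changed = True
        while changed:
            changed = False
            for i, sample_id in enumerate(out.samples):
                miss = np.flatnonzero(dos[i] == MISSING)
                if miss.size == 0:
                    continue
                if sample_id not in ped:
                    continue
                sire, dam = ped.parents_of(sample_id)
                sire_i = idx.get(sire) if sire in sample_set else None
                dam_i = idx.get(dam) if dam in sample_set else None
                kids = [
                    (idx[k], ped.parents_of(k))
                    for k in ped.offspring_of(sample_id)
                    if k in sample_set
                ]
                for j in miss:
                    cand = []
                    for d in (0, 1, 2):
                        s = dos[sire_i, j] if sire_i is not None else MISSING
                        da = dos[dam_i, j] if dam_i is not None else MISSING
                        if not _TRIO_OK[s + 1, da + 1, d + 1]:
                            continue
                        ok = True
                        for ki, (ks, kd) in kids:
                            kdos = dos[ki, j]
                            if kdos == MISSING:
                                continue
                            other = kd if ks == sample_id else ks
                            other_dos = (
                                dos[idx[other], j]
                                if other in sample_set and other is not None
                                else MISSING
                            )
                            if ks == sample_id:
                                trio_ok = _TRIO_OK[d + 1, other_dos + 1, kdos + 1]
                            else:
                                trio_ok = _TRIO_OK[other_dos + 1, d + 1, kdos + 1]
                            if not trio_ok:
                                ok = False
                                break
                        if ok:
                            cand.append(d)
                    if len(cand) == 1:
                        dos[i, j] = cand[0]
                        prov[i, j] = PROV_PEDIGREE
                        changed = True
    still = dos == MISSING
    if still.any():
        rng = np.random.default_rng(seed)
        called = dos != MISSING
        n_called = np.maximum(called.sum(axis=0), 1)
        p_alt = (dos * called).sum(axis=0) / (2.0 * n_called)
        draws = (
            (rng.random(dos.shape) < p_alt).astype(np.int8)
            + (rng.random(dos.shape) < p_alt).astype(np.int8)
        )
        dos[still] = draws[still]
    out.dosage = dos
    return out, prov


# ---------------------------------------------------------------------------
# Functional wrappers and the external-tool adapter


def frequency_fill_impute(task: ImputationTask, mode: str = "allele") -> ImputationResult:
    est = FrequencyFillImputer(mode=mode, random_state=task.seed)
    return est.fit(task.reference).transform(task.target)


def family_ld_impute(
    task: ImputationTask,
    window_sizes: tuple[int, ...] = (64, 16, 4),
    overlap: float = 0.5,
) -> ImputationResult:
    est = FamilyLDImputer(
        window_sizes=window_sizes, overlap=overlap, random_state=task.seed
    )
    return est.fit(task.reference, task.pedigree).transform(task.target)


def run_external_imputer(task: ImputationTask, cmd_template: str) -> ImputationResult:
    """Adapter for an external imputation executable.

    Writes the reference panel, target panel and pedigree to temporary
    files, substitutes ``{ref}``, ``{target}``, ``{ped}``, ``{out}`` and
    ``{seed}`` into ``cmd_template``, runs it and parses the returned VCF.
    """
    from .vcfio import read_vcf, write_pedigree, write_vcf

    with tempfile.TemporaryDirectory() as tmp:
        tmp_p = Path(tmp)
        ref_path = tmp_p / "reference.vcf"
        tgt_path = tmp_p / "target.vcf"
        ped_path = tmp_p / "pedigree.tsv"
        out_path = tmp_p / "imputed.vcf"
        ref_gm = task.reference.to_genotype_matrix()
        write_vcf(ref_gm, ref_path, haps=task.reference)
        write_vcf(task.target, tgt_path)
        if task.pedigree is not None:
            write_pedigree(task.pedigree, ped_path)
        else:
            ped_path.write_text("id\tsire\tdam\tclass\n")
        cmd = cmd_template.format(
            ref=ref_path, target=tgt_path, ped=ped_path, out=out_path,
            seed=task.seed,
        )
        try:
            res = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
        except OSError as exc:  # pragma: no cover
            raise RuntimeError(f"external imputer failed to start: {exc}") from exc
        if res.returncode != 0 or not out_path.exists():
            raise RuntimeError(
                f"external imputer exited with {res.returncode}; "
                f"stderr:\n{res.stderr[-2000:]}"
            )
        imputed = read_vcf(out_path)
        if isinstance(imputed, tuple):  # pragma: no cover
            imputed = imputed[0]
    for s in task.target.samples:
        if s not in imputed.samples:
            raise RuntimeError(f"external imputer output lacks sample {s!r}")
    imputed = imputed.take_samples(list(task.target.samples))
    chip_idx = target_site_indices(imputed, task.target)
    prov = np.full(imputed.dosage.shape, PROV_HAPLOTYPE, dtype=np.uint8)
    if (chip_idx >= 0).all():
        observed = task.target.dosage != MISSING
        pcol = prov[:, chip_idx]
        prov[:, chip_idx] = np.where(observed, PROV_OBSERVED, pcol)
    return ImputationResult(imputed=imputed, provenance=prov)
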