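# Methods

This note documents the models, defaults and numerical choices behind
`pedimpute`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Study design emulated by the generator

The generator reproduces the structure of a poplar breeding study: an
almost-complete factorial mating set (4 females × 4 males, 14 of the 16
crosses, 413 F1 progenies), a multiple-pair mating set (8 females × 7 males,
21 crosses, 598 progenies) whose two first females are themselves factorial
progenies (dual-role individuals), six unrelated accessions and one
grandparent — 1039 individuals, 23 distinct parents, 35 families. The
"sequenced" reference subset holds 43 individuals: the grandparent, all 23
parents (including the two dual-role females), 13 progenies chosen by greedy
set cover so that every parent has at least one sequenced offspring, and the
6 unrelated accessions. Family sizes (30/29 and 29/28 per cross) are split
evenly because only the totals of the design are specified.

## Founder haplotypes and linkage disequilibrium

Founder haplotypes are generated by a first-order Markov latent-uniform
process: each haplotype carries a latent uniform that persists from one site
to the next with probability `ld_rho` (default 0.998) and is redrawn
otherwise; the allele is the indicator {u < p_s}, with per-site alternative
allele frequencies p_s ~ Beta(0.5, 0.5). This yields geometrically decaying
pairwise LD with a tunable scale — at the default 2,500-bp mean site spacing
the latent state refreshes about every 1.25 Mb, so D′ is high below ~1 Mb
and decays beyond, a plausible scale for an outbred tree population with a
modest effective number of founders. A coalescent simulator would give a
demographically grounded LD structure, but imputation only requires that LD
exists and decays monotonically; the Markov process is seconds-fast, exactly
seedable and has a single interpretable knob.

Gene dropping transmits one recombinant gamete per parent down the pedigree
in topological order. Crossovers follow the Haldane model: the count per
gamete is Poisson(recomb_rate × length_Mb / 100) with uniform breakpoints
and no interference; the default 2 cM/Mb on 50-Mb chromosomes gives one
crossover per gamete on average. Half-founders (the grandparent's unknown
mate) draw a fresh pool haplotype for the unknown side. Offspring genotypes
are therefore Mendelian-consistent and fully phased by construction;
haplotype 0 is paternal.

## Panels, depth, quality and errors

The chip is a subset of sequence sites selected per equal-width bin as the
highest-MAF site with MAF ≥ 0.1 (`chip_maf_floor`), emulating an array
enriched in common variants. Real array designs are also heterogeneous in
density, and that heterogeneity is what gives the local chip/sequence
density ratio its explanatory power, so by default per-bin marker counts
are Dirichlet(α = 2)–multinomial rather than exactly one per bin; setting
`chip_density_alpha = None` restores even spacing.

Per-individual mean coverage is lognormal with mean 13X clipped to [4, 52]
(σ = 0.45), per-cell depths are Poisson around the individual mean, and QUAL
is Gamma(4, 15) with a floor at zero — matching the coverage range of a
typical medium-coverage resequencing effort. The chip panel carries 1%
missing genotypes by default (`missing_rate_chip`), removed before
imputation by a Mendelian-deduction-then-frequency pre-pass
(`fill_chip_missing`).

Genotype errors enter the pipeline through the dual-caller filter stage: the
filter cascade is demonstrated on two independently error-injected copies
(0.5% per-genotype flips) of the sequenced panel, standing in for two
variant callers, and removes low-quality, monomorphic, caller-discordant and
Mendelian-inconsistent sites. The evaluation panels themselves are the
error-free phased truth restricted to the cascade's surviving sites: the
real study's reference was the post-filter consensus of two callers, and the
imputation experiment asks how well haplotypes propagate, not how noisy the
calls were.

## Imputers

`FrequencyFillImputer` draws each unobserved allele Bernoulli(p_alt) from
the reference panel (two draws per genotype), the construction whose
expected per-site concordance against an HWE truth is Σ_g p_g q_g — 0.375 at
allele frequency ½ — and which therefore serves as the lower bound for any
imputer that uses linkage or pedigree information. A genotype-frequency
variant (`mode="genotype"`) is available because the chance term of cProps
is defined on genotype frequencies.

`FamilyLDImputer` is a windowed haplotype-library matcher — a documented
stand-in for pedigree+LD imputation tools whose internals are unpublished,
not a reimplementation of any of them. Per chromosome it: (1) phases the
target's chip genotypes where a reference parent is homozygous; (2) slides
windows of W chip markers (defaults W = 64, 16, 4, each with 50% overlap,
largest first; terminal windows extend to the chromosome ends) and searches
for diplotypes: pairs of reference haplotypes whose allele sum equals the
observed chip dosage at every called window site and which satisfy the
phase constraints — so an unphased heterozygous site has both phase
configurations tried. Candidates are searched in relative tiers, nearest
first: the transmitting parent (paternal haplotype → sire), the other
parent, grandparents, offspring, then the whole panel; the offspring tier is
what lets a parent be imputed from its sequenced children, mirroring a
reference set chosen so every parent has a sequenced offspring. (3) The
matched haplotypes vote per spanned sequence site; an exactly split window
abstains. Votes combine by overall majority, ties resolved by the
smallest-window majority, then by the closest-relative-tier vote, then by
rounding the reference allele frequency. (4) Sites never covered by any
match are frequency-filled. Matching is exact (no mismatch tolerance);
window sizes and overlap are configuration, as the real tools' settings for
any given study are not published. Per-cell provenance (observed /
pedigree-deduced / haplotype-copied / frequency-filled) is recorded.

Both imputers follow the scikit-learn estimator protocol (`fit`/`transform`,
`get_params`/`set_params`, fitted attributes with trailing underscores); the
rest of the pipeline is function-shaped because filtering, scoring and
profiling are not fit/predict problems.

## Evaluation

Leave-one-out masking: each of the 43 reference individuals in turn has its
sequence genotypes masked, keeps its chip genotypes and is imputed from the
remaining 42; extra chip-only targets can be imputed in every fold, with a
rounded-mean consensus reported. Metrics are computed per individual ×
chromosome (Propi, Cori) and per SNP (Props, Cors, cProps, lbProps, Nᵢ).
The genotype-match indicator compares dosages by default; an allele-level
variant crediting half-right heterozygotes is available (`mode="allele"`).
cProps uses reference genotype frequencies from the reference truth and
validation frequencies from the imputed genotypes; it is not floored at
zero, and sites where chance = 1 are NA. Cors is NA whenever either vector
is constant — expected for rare alleles that impute to monomorphic — and
those sites are counted rather than dropped silently. High-quality SNP
selection uses strict thresholds Props > 0.9 AND cProps > 0.8.

The HWE exact test uses the standard two-sided construction (no mid-p):
heterozygote-count probabilities conditional on allele counts via the
recurrence relation, summing all outcomes no more likely than the observed
one (ties included with a 1e-12 relative tolerance); monomorphic samples
give p = 1. Density-ratio windows are anchored at coordinate 1,
half-open [k·500kb + 1, (k+1)·500kb]. D′ is reported as |D′|; the
distance-window profile weights pairs by the product of the two MAFs, the
only per-pair frequency quantity available (a `uniform` option exists, and
this choice is ours, not prescribed).

## Default problem sizes

Simulations default to 2 chromosomes × 20,000 sequence sites with
chip_fraction 0.005 (≈100 chip markers per chromosome) and the full
1039-individual design — small enough that a ten-replicate evaluation suite
runs in minutes on one core while keeping every structural feature of the
study (family sizes, reference composition, density contrast). LD profiling
subsamples the sequence panel to ≤600 sites per chromosome before pairing.

## What the synthetic tests do and do not show

The generator reproduces the study's pedigree structure, two-density
panels, depth/quality heterogeneity and chip missingness, so the pipeline's
qualitative findings on it — family/LD imputation dominating the frequency
lower bound, accuracy ordered by relatedness (progenies > parents >
unrelated), Propi and Cori nearly collinear, and the local chip density
(RatioDensity) as the strongest per-SNP factor — mirror the structure such
studies report. It does not model calling noise in the reference, reference
bias, statistical-phasing error or a real demographic history, and its rare
variants are as strongly locally correlated as common ones.

One documented consequence: in these conditions the imputed sequence panel
shows slightly *higher* long-range D′ than the chip panel, not lower. The
chip is composed of the most common variants, which carry the lowest |D′|,
and haplotype-copy imputation mildly amplifies long-range LD (the imputed
panel exceeds even the true sequence panel). Observing the opposite —
sequence-panel LD below the chip's — requires decorrelating processes on
sequence rare variants (calling and statistical-phasing errors) that are
deliberately outside this package's scope. The LD comparison is still
computed and reported; its direction should be interpreted with this in
mind.

## Degenerate inputs and tie-breaks

Metrics return NA (never 0) when undefined: all-missing truth rows, zero
variance for correlations, chance = 1 for cProps, monomorphic columns for
D′. The MISSING sentinel (−1) is distinct from every valid dosage and is
skipped explicitly everywhere. Filter steps are individually idempotent and
report in/removed/out counts that chain exactly. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; the end-to-end
`run-all` output is byte-identical across runs at a fixed seed.

## Known limitations

- The family/LD imputer is desk-scale: exact matching without a mismatch
  tolerance degrades if reference genotyping errors are introduced.
- Triallelic sites are carried through I/O, filtering and the Mendelian
  check (allele-identity based), but the imputers and LD operate on
  biallelic dosages/haplotypes.
- Gene-annotation profiling implements the single-nucleotide and simple
  indel effect classes only; complex substitutions are counted
  "unclassified".
- The external-imputer adapter shells out and re-reads VCF; it assumes the
  tool preserves sample names and site coordinates.
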