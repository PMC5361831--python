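# Methods

This note records the models behind each component, the tunable
parameters and their defaults, the numerical choices made where the
design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## Serotonin endophenotype

Whole-blood serotonin (WB5HT, ng/mL, carried opaquely) is standardized
as z = (raw − m̄)/s̄ against a user-supplied reference table of means
and SDs per (ancestry, pubertal stage) cell; for subjects reporting
several ancestries, m̄ and s̄ are the arithmetic means of the
per-ancestry reference moments.  Pubertal status uses Tanner stage when
available (I–II pre, ≥III post) and otherwise the age rule (pre below
144 months, post at or above).  When both Tanner and age are present,
Tanner wins: it is the direct clinical measurement the age rule only
proxies.  Group cut-points are z > 1.75 (High-5HT) and z < 1
(Normal-5HT); values at exactly 1.0 or 1.75 fall in the excluded
Intermediate band, since both defining inequalities are strict — this
boundary convention is fixed here so that group counts are
reproducible.  Subjects on serotonin-altering medication are excluded
before normalization.  Reference norms are always external inputs; the
package never estimates them from the cohort being analysed.

## Trio QC and de novo detection

Site-level QC keeps biallelic SNVs with a PASS filter tag and mean
depth strictly above 10, where "mean depth" is the site mean across
all cohort samples (a site-level reading consistent with VQSR-era QC;
the alternative per-member reading is stricter and not used).
Genotype-level QC masks any trio member with fewer than 6 reads.
Multi-allelic records are rejected at read time.  Both filters are
idempotent.

De novo variants are deterministic Mendelian violations: child alt
call with both parents confidently hom-ref on autosomes, the female X,
and the male X inside the pseudoautosomal regions (GRCh37 PAR
coordinates are the built-in default and configurable); on the male X
outside the PARs the child is hemizygous, so any alt call with a
hom-ref mother is de novo and the father is ignored.  A
genotype-likelihood caller would weigh read evidence at each of these
steps; the rule-based detector is the appropriate model for genotypes
that are already hard calls, and is exactly invertible against the
generator's planted truth, which is what the validation suite
exploits.  A missing required member always suppresses the call rather
than guessing.

## Recessively acting variants

Phase by transmission resolves each child alt allele to a parent using
only trio genotypes: a het child is phased when exactly one parent
carries the alt; a hom-alt child received one allele from each carrier
parent; both-carrier het children and any configuration with a missing
member are ambiguous; Mendelian-impossible configurations are flagged
inconsistent and excluded.  Ambiguous sites never support a compound
het — discarding unresolvable sites is the conservative reading of
"robust phasing" for rare variants, where both-carrier parents are
rare anyway.

Qualifying variants are autosomal (compound-het logic is inapplicable
in hemizygous males, so the X is excluded entirely), MAF < 0.01, and
LoF or missense with DScore ≥ 2 ("Mis-D2", by analogy with the
explicit Mis-D4 = DScore ≥ 4 convention).  A gene emits at most one CH
per proband regardless of extra qualifying hets, avoiding
combinatorial double counting; homozygote calls are per qualifying
site.

Burden is normalized by the synonymous baseline: per individual,
(functional + 1)/(synonymous + 1) qualifying genotype counts (+1
pseudo-counts keep zero-count individuals defined), compared between
probands and parents by a two-sided Mann–Whitney test.  Parents have
no grandparental genotypes, so trans-phase is unknowable for them;
burden therefore counts qualifying variant genotypes (one per het, two
per hom-alt) identically for every role, keeping the comparison
like-for-like.

Per-gene association between RAV carrier status and 5-HT group uses
Fisher's exact test on the proband-level 2×2 table (a proband counts
once per gene; the margins must be proband counts for the table to be
well-formed).  The odds ratio is the cross-product ratio with
Haldane–Anscombe 0.5 added to all cells when any cell is zero; genes
with OR > 1 are candidates, OR < 1 controls, OR = 1 neither.

## Length-matched gene-set enrichment

Candidate lists derived from observed variants are length-biased, and
brain-expressed gene sets are long-gene-enriched, so the naive
hypergeometric overlap test is anti-conservative.  The empirical null
replaces each candidate with a uniform draw from its window of up to
`interval` shorter and `interval` longer neighbours in the
CDS-length-sorted gene table (window clipped at the ends, the
candidate itself excluded, replacements within a pseudo-set kept
distinct by redraw with a full-row restart when windows are crowded).
Ties in CDS length are broken by a stable sort on gene symbol so ranks
are deterministic.  The default interval is 100; 30 and 1000 give the
same enrichment rank ordering in the test suite's designs.  The
empirical p uses the add-one estimator (#{null ≥ observed}+1)/(n+1),
which never returns zero; the upper-tail hypergeometric p is reported
alongside as the uncorrected reference value.  The default null size
is 1000 draws, a CLI knob — resolving p-values near 1e-5 requires on
the order of 1e5 draws.

Two properties of this null are worth knowing.  First, with an
integer-valued statistic the add-one estimator is conservative under
heavy ties, so calibration checks need overlap distributions with
enough spread (the validation suite uses candidate sets of several
hundred genes for this reason).  Second, at the extreme ends of the
length ranking the sampling window is clipped one-sided, so candidate
sets concentrated in the top few hundred ranks are matched slightly
toward the interior; with heavy-tailed CDS lengths this is visible if
candidates are weighted by raw length rather than rank.  Both effects
are properties of any windowed matching scheme, not implementation
artefacts.

## Network propagation (NGSEA / PDN)

Seeds (known disease genes) receive uniform weight 1/|seeds in
network| — uniform weighting makes summed scores comparable across
seed sets of different sizes — and flow diffuses by random walk with
restart, f_{t+1} = (1−α)·W·f_t + α·f_0, α = 0.3, iterated from f_0 to
an L1 change below 1e-9 (max 1000 sweeps; non-convergence raises).
The converged flow matches the direct solve of (I − (1−α)W)f = αf_0 to
1e-6, and total flow is conserved to 1e-8 on graphs without isolated
nodes.

W is the column-stochastic normalization of the binary adjacency
(zero-degree columns left zero).  The propagation recurrence is often
written with the raw 0/1 adjacency, but that iteration diverges
whenever the spectral radius of (1−α)A exceeds one — true for any
realistically sized interaction network — so normalization is
required and column-stochastic is the standard random-walk choice.
This is the single most consequential gap-fill in the package:
published p-values computed on a particular network snapshot are not
bit-reproducible without knowing the original normalization and seed
weighting.

A candidate's PDN (propagation-based distance in network) is the flow
it receives; the test statistic is the summed PDN of the candidate
list, excluding candidates that are themselves seeds (the statistic
measures novel genes' proximity to the established set) and counting
candidates absent from the network as zero.  Pseudo-candidates that
land on seeds are likewise zeroed.  Significance uses the same
length-matched pseudo-set machinery as the overlap test.

## Group-wise TDT

Every heterozygous parent at a qualifying site (autosomal, MAF < 0.01,
LoF or missense DScore ≥ 4) contributes one informative event: T if
the child received the minor allele, U otherwise.  With both parents
het the child genotype resolves the two events jointly (hom-ref child
U+2, het T+1/U+1, hom-alt T+2) — counting by allele numbers rather
than phase maximizes informative events without phase assumptions, and
such sites are rare below MAF 0.01.  Hom-alt parents are
uninformative; missing members skip the trio at that site;
Mendelian-impossible configurations are skipped; a site counts once
per group even when its gene carries several group annotations.

The test is the exact two-sided binomial against 0.5: doubled smaller
tail, capped at 1.  For the symmetric null this equals the
minimum-likelihood two-sided test, and on counts of 1:9 it gives
22/1024 = 0.02148.  Counts of 26:13 give 0.053 here; a χ²-approximate
TDT gives 0.037 on the same counts, and haplotype-based group tests
different values again — the statistic in use must be stated when
comparing published group-TDT p-values, which is why this package
pins and documents the exact binomial.  Synonymous variants run
through identical machinery as the negative control and are reported
side by side.

## Synthetic data: what it emulates, and what it does not

The generator produces a multi-sample trio VCF 4.2 (GT:DP), 6-column
PED, annotation TSV (gene, ANNOVAR-style consequence, DScore 0–9,
MAF), gene model with CDS lengths and RPKM, GMT gene sets, an
edge-list network, and phenotype/norms tables.  Defaults emulate a
116-trio exome cohort: ~60× depth (per-genotype depths Poisson(60),
with an optional fraction forced below 6 to exercise masking), rare
MAFs log-uniform on [5e-4, 0.01] (rare but observable at ~100 trios),
CDS lengths log-normal with median 1.5 kb and σ_log 0.8 (a heavy right
tail so long-gene candidate sets exist), ~85% of genes with RPKM > 1,
a 5.44:1 male:female proband ratio, roughly one functional de novo
variant per proband (16% LoF), 1.2 compound-het and 0.36 homozygote
genes per proband, and 28% of probands drawn from the elevated
serotonin component (centred 2.8 reference SDs above the reference
mean, SD 0.8, so ~90% of that component exceeds z = 1.75).

Parents are in Hardy–Weinberg at each site's MAF; children follow
Mendelian transmission except planted events.  Planted de novo sites
have all-hom-ref parents; planted compound hets are one
paternal-origin and one maternal-origin rare functional het by
construction; designated distorted genes transmit functional minor
alleles with a configurable probability while their synonymous alleles
stay at 0.5 (the built-in negative control).  Networks are
Barabási–Albert backbones, optionally with a planted clique wired to
anchor genes.  Everything is bit-reproducible under a fixed seed, and
the emitted VCF round-trips through the cyvcf2-based reader without
loss.

Not modelled: sequencing error and genotype-likelihood uncertainty,
linkage disequilibrium between sites, indels and multi-allelic sites,
population substructure within an ancestry label, and realistic
protein-network topology beyond scale-free degree structure.
Passing the planted-truth tests therefore demonstrates the logical
correctness of the detectors and tests, not their robustness to
genotyping error — on real data the upstream caller's quality model
carries that weight.

## Validation designs and problem sizes

The validation suite and `scripts/acceptance.py` use these designs,
chosen to make each property measurable at desk scale:

- Exact-value anchors: binomial gTDT on 1:9 counts; two-node RWR flow
  (0.5882, 0.4118) from the closed form α(I−0.7W)⁻¹f_0.
- Solver agreement: 50 random graphs up to 200 nodes, iterative vs
  direct solve, tolerance 1e-6; flow conservation on connected
  Watts–Strogatz graphs, tolerance 1e-8.
- Oracle equivalence: RAV calls vs exhaustive per-gene enumeration on
  1000 random trios; Fisher p vs rational-arithmetic hypergeometric
  enumeration for all 2×2 tables with group sizes ≤ 20; binomial p vs
  full-pmf enumeration for all T+U ≤ 60.
- Planted recovery: 100 noise-free trios, sensitivity 1.0 and zero
  false positives required for both detectors.
- Null calibration: 500 replicates at 200 null draws each.  The GSEA
  design uses a 20k-gene universe, 500 candidates sampled with
  probability ∝ CDS length, and a stochastic length-biased set
  (membership probability rising from 0.35 to 0.65 with length rank) —
  stochastic so that membership is not a deterministic function of
  rank, which would make the matched statistic degenerate, and with
  enough overlap variance that tie-discreteness sits below KS
  resolution.  The NGSEA design uses 5000 genes with a noisy monotone
  degree–length coupling and linear-in-rank candidate weighting.  Both
  require KS uniformity of the matched p at level 0.01 while the
  unmatched test's median p falls below 0.4.
- Length matching: 100 candidates sampled from the top length decile
  of a 20k-gene universe, 200 pseudo-sets, mean CDS length within 10%.
- gTDT operating characteristics: 2000 null cohort replicates (40
  trios, 3-gene group) for type-I ≤ 0.05; 300 distorted replicates
  (120 trios, transmission probability 0.85), power ≥ 0.9 conditional
  on ≥ 40 informative events.
- End-to-end contrast: 50 runs of a 100-trio, 1200-gene study where
  High-5HT probands draw their de novo variants from a 15-gene module
  wired next to a 25-gene seed set; the network enrichment must flag
  the High group's list (p < 0.05) in ≥ 80% of runs and the Normal
  group's in ≤ 10%.

## Known limitations

- DScore is consumed as an integer annotation; the nine underlying
  deleteriousness predictors are out of scope.
- The hemizygous male-X de novo rule is this package's convention;
  callers that code male X genotypes differently may disagree at the
  margin.
- The Fisher carrier unit is proband-level by design; event-level
  counting would need different margins and is not offered.
- No multiple-testing correction is applied anywhere; reports carry
  the number of tests run and nominal p-values.
- The gTDT is a single-site pooled test; haplotype-level multi-site
  transmission models are out of scope.
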