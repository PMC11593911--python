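# Methods

`snpimpute` is a self-contained, desk-scale re-enactment of a forensic SNP
imputation performance study: degrade complete genotype profiles the way
forensic samples degrade, impute the missing genotypes from a phased reference
panel, call imputed genotypes at a genotype-probability threshold, and measure
what that buys and what it costs.  This note records the models, the defaults
and why they are what they are, and what the synthetic world does and does not
show about real data.

## The imputation model

Imputation uses a diploid Li–Stephens haplotype-copying hidden Markov model.
The hidden state at site *m* is an ordered pair *(i, j)* of reference
haplotypes from the K-haplotype panel; the two chains move independently with
the exchangeable kernel

&nbsp;&nbsp;&nbsp;&nbsp;τ(d) = 1 − exp(−4·Ne·(d/100)/K)

per gap of *d* cM (stay with probability (1−τ) + τ/K, jump to each specific
haplotype with probability τ/K).  The observed (unphased) genotype at a typed
site is emitted from the copied allele pair through a per-allele miscopy
probability ε: P(x|a) = 1−ε if x = a, else ε; homozygous emissions multiply
the two per-allele terms, the heterozygous emission sums both orderings, and a
missing site emits 1.  A scaled forward–backward pass over the K² states gives
the exact posterior over the three diploid genotypes at every site, in
O(L·K²) time via the rank structure of the transition kernel, with
√L-checkpointed recomputation so memory stays at O(√L·K²).  Reported per site:
the posterior triple (p₀, p₁, p₂), the ALT dosage p₁ + 2p₂, and the genotype
probability GP = max(p₀, p₁, p₂).  Argmax ties break toward the lower genotype
code for determinism.

Calling is a single inclusive rule: a missing site is imputed with its argmax
genotype when GP ≥ Q_gp ("met or exceeded"); typed sites always pass through
unchanged.

Working directly on unphased genotypes with an exact pair-state
forward–backward (rather than a phase-then-impute pipeline as production
imputation tools use) removes a stage, makes small instances checkable against
exhaustive path enumeration, and makes the GP an exact model posterior.  A
consequence worth knowing: this GP can be *better calibrated* than the
genotype probabilities of iterative phasing/imputation software.

Defaults: **Ne = 10,000** — the conventional human-scale value for this
parameterization of the copying model (production tools that quote much larger
Ne values attach them to differently parameterized state spaces, so those
numbers do not transfer; at Ne = 10⁶ this K≈200-state model would switch
almost every site and carry no linkage information).  **ε = 10⁻³**, with the
Watterson-heuristic alternative ε = θ/(2(θ+K)) behind a flag.  Both are
exposed in `HMMParams` / `BenchmarkConfig`.

## The synthetic world

No external data are required; the generator emulates the ingredients the
study needs.

**Founders.** `simulate_founders` draws per-site ALT frequencies from
Beta(0.8, 0.8) truncated to [maf_min, 1−maf_min] (default maf_min = 0.02) and
fills a founder matrix with independent Bernoulli columns, redrawing any
column below the minor-count floor.  The near-uniform Beta keeps rare alleles
scarce, matching targeted forensic SNP panels, which are designed around
common markers; the spectrum is configuration, not dogma.  Sites sit on one
synthetic chromosome with ~1 kb mean spacing and a linear genetic map
(default 1 cM/Mb), so 20,000 sites span ~20 Mb ≈ 20 cM — a chromosome-22-like
geometry.

**Panel LD.** `recombine_panel` expands the founders into panel haplotypes
that copy one founder at a time and switch founders as a Poisson process on
the cM axis (`n_generations` switches per Morgan; default 100, i.e. ~1 cM
founder blocks).  Mosaic copying from a finite founder pool is precisely the
dependence structure a haplotype-copying imputer exploits, which is the point:
the study needs LD the HMM can use, not coalescent realism.  `n_generations=0`
returns balanced copies of the founders (cycled), conserving frequencies
exactly when the output count is a multiple of the founder count.

**Populations.** `split_populations` realizes a target Fst *F* per population
by drawing site frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F) around the founder frequency p, shifting the
*shared* founder matrix to those frequencies by exact-count allele flips, and
re-simulating each population's haplotypes as mosaics of its perturbed
founders.  Flipping entries of the shared founder matrix (instead of
re-simulating sites independently) preserves the founder haplotype backbone,
so populations share long-range haplotype structure — without that,
cross-population imputation would be impossible and the panel-composition
experiment meaningless.  Hudson's ratio-of-averages estimator is used to
verify the realized Fst (unbiased for F here, simpler than full
Weir–Cockerham, and equivalent for equal-size haploid samples).

**Test individuals.** `sample_truth_individual` picks two panel haplotypes
without replacement and reports their rows for exclusion from the reference.
The benchmark flips its `recombine` option on: each truth haplotype is then
re-sampled as a copying-process mosaic of the *other* eligible haplotypes,
using the same τ formula as the engine.  Rationale: a real test sample removed
from the panel it was drawn from is a recombinant relative of the remaining
donors, not a literal copy of two of them.  The literal-copy shortcut makes
the copying model mis-specified in a way that leaves the exact posterior
measurably overconfident (GP 0.93 sites were right far less than 93% of the
time), which would poison every GP-threshold analysis; with recombinant truth
the GP is empirically calibrated to within a percentage point.  Population
tags restrict the mosaic to the focal population's haplotypes, so two-pop test
individuals have single-population ancestry.

**Degradation.** Pruning keeps a uniform random subset of exactly `n_target`
sites (or a fraction).  Drop-in then turns each typed homozygote into a
heterozygote with probability 0.1 (the default rate); drop-out turns each
typed heterozygote into a homozygote for a uniformly chosen surviving allele
with probability 0.1.  Drop-in is limited to homozygotes by definition of the
artifact (one spurious extra allele; it never flips hom-ref to hom-alt), and
drop-out of one of two identical alleles is unobservable, so only
heterozygotes can change.  Rates are interpreted per *genotype*; a per-allele
drop-out mode (each allele lost independently, conditioned on one surviving so
a typed genotype never becomes missing) is available behind a flag.  All
per-site draws are counter-based hashes of (seed, stage, site position), so
degradation commutes with site reordering and every stage replays
independently.  Errors are injected after pruning — they are properties of the
typed data.

## Metrics and aggregation

Call rate = (observed + imputed genotypes) / total targets.  Error rate =
erroneous assigned genotypes / (observed + imputed), with 0/0 defined as 0
(warned).  Counts are exact integers; the division happens once.  Injected
observed errors count in the numerator by default — an assigned genotype that
disagrees with the truth is wrong however it got there — with a flag to
restrict the numerator to imputed calls for sensitivity analysis.  Replicates
aggregate as median / min / max per design cell (even-count median = mean of
the central pair).  Chromosome-scale counts extrapolate linearly to a
genome-wide target total (default 1.3 M); rates are unchanged by construction,
and real chromosome-to-genome transfer error (~10% in comparable studies) is
not modelled.

## The design matrix

Defaults divide the genome-scale study by 65: 20,000 target sites stand in for
chromosome 22's share of 1.3 M genome-wide targets; the observed-count ladder
{400, 1,000, 5,000, 10,000} preserves the observed fraction of targeted panels
between 4,000 and 300,000 markers; thresholds {0.5, 0.9, 0.95, 0.99}; 10
replicate individuals per cell; 200 panel haplotypes from 100 founders.  One
panel and one set of replicate individuals are shared across the cells of an
experiment (only pruning and error seeds vary per cell), mirroring a fixed
reference panel and fixed test-sample sets; comparisons along a ladder are
therefore paired.  Seeds derive from the master seed through a counter-based
splitter keyed on (stage, cell labels, replicate): any cell re-runs in
isolation, removing a cell changes nothing else, and matched comparisons
(error modes; panel composition) share panel/truth/pruning seeds by
construction, differing only in the stage under study.  At these sizes the
full matrix runs in minutes on one core; all sizes are configuration.

## What passing here does and does not show

The synthetic world is a controlled approximation.  It shows that the
engine's posteriors are exact (they match exhaustive path enumeration), that
the GP behaves like a probability under a correctly specified relative
structure, and that the qualitative effects — more observations help, higher
thresholds trade coverage for accuracy, drop-in hurts more than drop-out,
missing reference populations hurt accuracy — emerge from the mechanism
itself.  It does not reproduce real human haplotype diversity: no coalescent
genealogy, no mutation/gene-conversion, no allele-frequency spectrum realism
beyond the configured Beta, no multi-chromosome variation, and panel sizes two
orders of magnitude below real reference panels.  Absolute call/error levels
therefore do not transfer to real panels; directions and mechanisms do.

## Numerical and edge-case choices

Posterior rows renormalize per site (≤10⁻⁹ deviation asserted at L = 10⁵);
messages rescale to unit mass, so nothing underflows.  Empty site lists,
n_target ∈ {0, L}, rate ∈ {0, 1} and single-population "splits" are all legal
degenerate inputs with forced outcomes.  Target sites absent from the panel
are unimputable (their alleles are unrepresented) and are flagged, not
guessed.  VCF rules: panels strictly phased "|", targets "/" with "./." for
missing; biallelic SNPs only, others skipped with a logged count; REF/ALT
mismatches between target and panel are hard errors — no silent allele
harmonization.  The genetic-map INFO field round-trips through `repr` so
panel files are bit-exact inverses of their in-memory objects.
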