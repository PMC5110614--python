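# Methods

This note documents the models, the generative assumptions of the
synthetic cohort, the numerical choices, and the limits of what the test
suite demonstrates.

## Study design being modelled

Two highly inbred strains descend, through selection and inbreeding, from a
heterogeneous stock founded by eight inbred strains. Five founders have
usable sequence; the remaining founders and the reference-like strain are
collapsed into a single *unknown/reference* ancestry class (the
reference-like founder is nearly invisible in SNP panels, and the
unsequenced founders cannot be told apart from each other). Each strain's
genome is a mosaic of founder haplotypes whose block structure reflects
recombination during breeding; because the strains are inbred, genotypes
are homozygous at ≥ 99.8% of sites and a haploid treatment suffices.

## Variant classification

Filters act per strain on a biallelic site's read evidence, in order:

| rule | constant | reason for rejection |
|---|---|---|
| depth | ≥ 5 reads in the asserting strain | `filtered_depth` |
| allele support | ≥ 90% of reads carry the alt | `filtered_het` |
| repeat proximity | > 5 bp from a repeat interval | `filtered_repeat` |

A site retained in both strains with the same alt is *common*; retained in
one strain it is a *candidate strain-distinct* variant and is checked
against the other strain's **raw, unfiltered** call: ≥ 3 reads with ≥ 50%
carrying the same alt demote the candidate (evidence the allele is present
but under-covered in the other strain). The pipeline therefore carries both
raw and filtered call sets. Classes are mutually exclusive and exhaustive;
when no strain's call survives, the class is the failure reason of the
strain with the stronger alt evidence. Multi-allelic records are decomposed
to biallelic ones on VCF input, so all rules are per variant allele; how
conflicting alt alleles at one position should be tallied in a combined
summary is genuinely ambiguous, and the per-allele report makes that choice
explicit.

Coding effects translate the affected codon (standard genetic code,
strand-aware) for SNPs — synonymous, non-synonymous, or premature stop —
and classify CDS indels by length change: frameshift iff not divisible by
three, otherwise in-frame insertion/deletion. Gene models whose CDS length
is not a multiple of three raise an annotation error and the variant is
reported unannotated rather than guessed.

## Ancestry hidden Markov model

**States.** One per sequenced founder plus `Unk/Ref`. **Observations.**
The per-site match pattern over {founders, reference}: indicator *j* is set
when the strain's allele equals founder *j*'s allele (or the reference
allele for the last indicator). Sites missing in the strain are skipped;
sites matching the reference and every founder can be thinned (they carry
no founder-discriminating signal), default keep-all.

**Emissions.** Bernoulli-product likelihoods over the indicators. Each
founder state has three parameters: self-match, pooled cross-founder match,
and reference match; the unknown state has two (pooled founder match,
reference match — the sequenced-founder indicators are exchangeable under
it). Two structural constraints make the states identifiable, both learned
the hard way on synthetic data:

* *Pooling the cross-founder indicators.* With fully free per-indicator
  emissions the labels are unidentifiable: EM happily co-opts an unused
  founder state to model a sub-segment of another founder's block, because
  nothing ties a state to "its" founder beyond initialization. Pooling
  means a state can only fit a segment well through its own founder's
  indicator.
* *A self-match floor (default 0.8).* A founder state whose founder is
  absent from the mosaic has no data of its own; unconstrained, its
  self-match drifts to the chance agreement level (~0.55) and the state
  becomes an impostor for the unknown state. Scientifically, a segment
  assigned to a founder must match that founder up to sequencing error and
  de novo mutation, so the floor encodes the state's meaning. Both
  constraints are implemented as the constrained maximizer in the M-step
  (the expected log-likelihood is separately concave per parameter), so the
  EM ascent property is untouched.

All probabilities are additionally clamped to `[error_floor, 1 −
error_floor]` with `error_floor = 0.01`.

**Transitions.** Over an interval of genetic length *d* Morgans (from a
piecewise-linear cM/Mb map integrated by the trapezoid rule, terminal rates
extrapolated flat), the chain switches with probability `1 − exp(−λ d)`,
mass divided uniformly among the other states. λ ("switch scale", expected
switches per Morgan) is one global scalar, fitted by a bounded 1-D
maximization of the expected complete-data transition log-likelihood inside
each M-step; the recombination map enters only through the interval
lengths. λ is bounded to `[1e−8, 1e4]`.

**Fitting and decoding.** Scaled log-space forward–backward (posterior
marginals sum to 1 within 1e−9 by construction); EM stops when the
log-likelihood gain drops below `tol` (default 1e−6) or at `max_iter`.
Viterbi ties break toward the lower-indexed state, deterministically. The
initial distribution is uniform and not re-estimated — a single chromosome
contributes one draw from it, so estimating it is noise. Chromosomes are
decoded independently.

**Haploblocks and IBD.** Maximal constant-state runs become blocks;
boundaries fall midway between flanking sites, the first block starts at 0
and the last ends at the chromosome length. A block decoded as founder *f*
is relabeled with the set of founders whose panel alleles are identical to
*f*'s across the block's sites — identical by descent, where single-founder
assignment is impossible. IBD is resolved post hoc at block granularity
rather than inside each EM iteration: the EM operates on the full state
space and the relabeling is a reporting-level operation, which keeps the
likelihood well-defined and the E-step exact.

**Validation.** Held-out indels (never shown to the HMM) are checked per
block: the fraction of strain indels inside the block that the labeled
ancestor — any member of an IBD set — also carries. Blocks with no indels
are *missing*, not zero; the genome-wide figure is the indel-count-weighted
mean.

## Strain genome construction

Variants are VCF-convention: 1-based, left-aligned, anchor-base style.
Application walks the reference once, emitting matched segments (equal
length, colinear) into a liftover table; SNP spans map 1:1, deleted
reference bases and inserted strain bases have no image. The table is
bijective outside variant spans and invertible by swapping coordinate
columns. Annotation boundaries inside a deleted span snap outward to the
nearest retained coordinate (keeping the maximal feature — conservative for
downstream read counting) and are flagged `boundary_adjusted`; features
entirely within a deletion are dropped and logged.

## Structural-variant selection

Same-type calls merge when their reciprocal overlap is ≥ 0.5 (union span,
supports summed per strain, source-strain sets united); translocations
match by both breakpoint pairs within ±600 bp and never by overlap
fraction; telomere-overlapping calls are excluded. The specificity score is
`other/(own+other)` with *own* the larger and *other* the smaller of the
two strain supports — 0 means no cross-strain evidence.

The published scoring formula and FDR estimator for this step were not
available, so the selection here is the package's own documented
construction, parameterized so alternatives can be swapped in:

* events called independently in both strains (*shared proxy*) are treated
  as known shared — they are never returned as strain-unique;
* sweeping cutoffs over the distinct scores, the estimated FDR at cutoff
  *c* is the fraction of proxy-shared events among all events scoring ≤ c,
  made monotone by a running maximum (so the search for the largest
  admissible cutoff is well-defined);
* the largest cutoff with estimated FDR ≤ the target (default 0.05) is
  selected; if none qualifies, the FDR-minimizing cutoff is returned with a
  warning flag.

The proxy calibrates how often shared events slip below a given cutoff,
estimating the contamination among kept events whose second-strain call was
missed. With zero cross-strain noise the selected set equals the generator
truth exactly; at the default noise level the realized truth-FDR stays
within 0.02 of the target on seeded runs.

## Landscape summaries

Window densities use 500 kb windows stepped every 100 kb (each variant
counted in every overlapping window; terminal windows keep their true
length in the density denominator). QTL assignment is by window midpoint by
default — overlapping windows would otherwise be double-counted — with a
`contained` mode that keeps only windows fully inside or fully outside QTL
intervals; the latter is what the enrichment measurements use, because
boundary-straddling windows mix both density regimes and bias the ratio
toward 1. Whether a density track should use all variants or only
strain-distinct ones is exposed as the caller's choice of input variant
set. The chance ancestry baseline for a group of *k* of *n* equally
represented founders is *k/n* (3 of 8 → 37.5%).

## Mapping-impact taxonomy

Read fates compare placements under the two genomes through the liftover
(same locus iff the strain position lifted back to reference coordinates
agrees within a tolerance, default 0 bp — the tolerance is configurable
since the right value depends on the aligner's clipping behaviour). DE
comparison applies the adjusted-p ≤ 0.1 rule per mapping; *borderline* —
not defined numerically in the underlying study design — defaults to the
non-significant p lying within 2× the cutoff, exposed as a parameter. This
module consumes DE results; it does not fit count models.

## Synthetic cohort

The generator emits fixtures in standard formats and a separate truth set
(never written into pipeline-consumed files). Key choices:

* **Read depth**: negative binomial, mean 30 (matching ~30× genome
  coverage), dispersion 3 — overdispersion stresses the depth filters; an
  optional floor supports noise-free runs.
* **Homozygosity**: 0.9987 of sites fixed, matching the ≥ 99.8% observed in
  highly inbred strains; heterozygous sites emit ~50% allele support and
  must be removed by the support filter.
* **Founder panel**: per-founder alt alleles at marginal frequency 0.35;
  contiguous founder-pair IBD runs (10% of sites, 100-site runs) exercise
  the relabeling; 15% of sites carry an alt only on the latent unknown
  haplotype (the unknown-founder signal), enforced exactly at that rate.
  The unsequenced founders are one latent haplotype, mirroring the combined
  unknown/reference state. Founder allele-frequency spectra are free
  parameters, not asserted as realistic.
* **Mosaic**: ancestry path switches per interval with probability
  `1 − exp(−λ d)`; defaults (λ = 20/Morgan on a 50 cM chromosome) give ~10
  expected switches. Genotype error flips alleles at 0.5%.
* **Indels for validation**: inherited from the true ancestor at each
  position, with ancestry taken constant up to inter-site midpoints (the
  same convention haploblock boundaries use), and with IBD founder pairs
  sharing indel carriers over their runs — a shared haplotype shares its
  indels.
* **SVs**: 200 events, half strain-unique; shared events are called in both
  strains with ±50 bp breakpoint jitter, unique events carry Poisson(0.3)
  cross-strain noise support; 10% redundant duplicate calls.

What the generator does **not** emulate: read-level artifacts (mapping
bias, duplicates, indel realignment), linkage-disequilibrium structure
within founders, population-scale allele-frequency spectra, multi-allelic
sites, or chromosome-specific effects (an X chromosome is not treated
specially). Passing tests therefore demonstrate the correctness of the
*rules and inference* under the stated statistical assumptions, not
robustness to real sequencing pathology.

## Problem sizes and numerical tolerances

Test and validation runs use a single 100 Mb chromosome with 600–20,000
sites depending on the check (5,000 for ancestry recovery — enough for
~500 sites per block at ~10 switches), 200 SV events, and 25–50 EM tracks;
exhaustive Viterbi oracles enumerate up to 6^8 paths. EM monotonicity is
asserted within 1e−8, Viterbi–oracle agreement within 1e−9, posterior
normalization within 1e−9. Ancestry accuracy is measured outside
IBD-ambiguous runs — sites whose true ancestor is indistinguishable from
another founder (or from the latent unknown haplotype) across its entire
true block — since no decoder can resolve those.

## Known limitations

* Ancestry blocks visited by the unknown state are identifiable only
  through sites where no founder matches; long reference-heavy stretches
  inside such blocks can be decoded as a chance-matching founder. The
  indel-consistency metric is designed to surface exactly this, and
  sparse tracks (≲ 1,500 sites per chromosome) show values of 0.95–0.99
  rather than 1.0 on some seeds.
* The switch scale is global; per-chromosome re-estimation is not
  implemented (decode per chromosome and fit separately if needed).
* Heterozygous/phased ancestry is out of scope — strains are treated as
  haploid, which is adequate only for highly inbred genomes.
* The SV score uses supporting-read counts; callers reporting other
  evidence types need their support mapped onto counts first.
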