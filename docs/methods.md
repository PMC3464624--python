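# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `copyevol`, in the spirit of a
statistical-software methods appendix. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Copy calling from clone libraries

**Error model and threshold.** Cloning separates individual PCR product
molecules, so each sequenced clone carries the polymerase errors of its own
amplification lineage. With a per-cycle error of 1/9000 per base and 35
cycles, the expected per-clone error is `expected_pcr_error(35, 1/9000) =
35/9000 ≈ 0.39%` of positions (linear accumulation — a deliberate upper
bound, since a sampled molecule's lineage is copied in only a subset of
cycles). Clones less than 1% different are therefore treated as the same
copy: twice the rounded-up per-clone error.

**Distance.** `pairwise_difference` is the proportion of differing
positions among comparable aligned columns; columns where either sequence
has `N` or a gap count in neither numerator nor denominator. Equal-length
pairs are compared column-wise without alignment. Unequal-length pairs are
globally aligned with unit-cost Needleman-Wunsch (edlib); the affine-gap
aligner (match +1 / mismatch −1 / open −5 / extend −1, Bio.Align) is
available via `method="affine"`. The edit-distance aligner was adopted for
all-pairs clone comparison because it is roughly two orders of magnitude
faster at ~1.7 kb and yields identical partitions: the <1% rule measures
substitution load, which both aligners count the same way on clone data
(indels only separate different intron architectures, which are far beyond
the threshold anyway).

**Clustering.** `collapse_clones` is single-linkage: clones are linked when
their pairwise difference is below the threshold and connected components
become copies, each reported as a per-column majority-rule consensus
(ties break to the alphabetically first base, so the output is independent
of input order). Single linkage is the natural closure of a pairwise
"same if < t different" relation, and the implementation is tested for
exact agreement with a brute-force connected-components oracle.

**Consensus-membership refinement.** Pure pairwise linkage is fragile
exactly at the PCR error scale: two clones of the same copy differ by about
twice the per-clone error, which is only ~1 standard deviation below the 1%
threshold, so sparsely sampled copies occasionally shatter into singletons
even though every clone is well within 1% of the copy's consensus.
`refine_copyset` therefore applies the same rule clone-to-copy: two called
copies merge when *every* member clone of the union lies within the
threshold of the union's majority consensus. For a genuinely single copy
the union consensus is essentially error-free (errors vote each other out)
and the test passes; for two distinct copies each clone sits roughly half
the copy distance plus its own errors away, and the merge is rejected. The
refined copy set is stable under a further pass, which is the operational
form of the idempotence property of collapse. A clone whose true error load
reaches 1% remains a separate copy — that residual overcount risk is
irreducible under this threshold rule, and mirrors what happens with real
libraries ("similar sequences just outside the error threshold").

**Richness.** `chao1` implements the abundance-based Chao1 estimator,
`S_obs + f1²/(2 f2)`, switching to the bias-corrected `S_obs +
f1(f1−1)/2` when no doubletons exist, with the classical variance for the
corresponding case (SE = 0 when `f1 = 0`). Accumulation curves resample
clone orderings and report the mean and 5–95 percentile band of distinct
copies per prefix; the mean curve is validated against the exact
hypergeometric expectation.

## Intron architecture

`locate_introns` globally aligns each genomic copy to an intron-free coding
reference and reports maximal insertions as introns. Scoring is match +1 /
mismatch −1 / gap open −12 / extend −0.5: the expensive open and cheap
extension keep a whole intron as one gap even when exons are 15–25%
divergent (with the generic −5/−1 scheme, long introns split around
chance-matching islands). When the aligner produces a mixed gap (reference
bases skipped alongside the insertion), the net insertion is anchored after
the skipped exon bases. Boundaries are then refined by sliding the
insertion up to ±15 bp to the nearest position with a canonical splice
motif, preferring the strong `GGT` donor over bare `GT`, with `AG` as
acceptor; insertions that still lack a motif are reported but flagged.
Insertions shorter than 4 bp are treated as exonic indels.

`canonicalize_sites` merges observed insertion points within 6 bp that
share a donor motif (canonical position = median); nearby sites with
*different* canonical donors remain distinct (the signature of an intron
translocation rather than one site). Flagged observations merge into a
nearby canonical site regardless of donor (they are noisy boundary calls),
and a site supported by a single copy within twice the merge window of a
site supported by three or more copies is absorbed into it — an automated
version of the manual curation such surveys apply.

`assign_classes` takes the distinct presence/absence vectors as pattern
variants and joins variants whose Hamming distance is at most 1 (single
intron gain/loss) into major classes; class ids order by descending
membership. `splice` removes the located intron segments and round-trips
exactly on noise-free synthetic copies.

## Protein chemistry

GRAVY is the mean Kyte–Doolittle hydropathy; the isoelectric point solves
the Henderson–Hasselbalch net charge for zero by bisection on pH ∈ [0, 14]
to 1e−4 (Bjellqvist pKa set, as in ProtParam; positive groups N-terminus,
H, K, R; negative C-terminus, D, E, C, Y); the instability index is
`(10/L) Σ DIWV(x_i, x_{i+1})` over dipeptides with the Guruprasad weights,
< 40 predicted stable. The scale tables are imported from Biopython's
ProtParam data (the published sources), and the implementations cross-check
against Biopython's independent ones in the tests. Unknown residues are
skipped for GRAVY/pI and break dipeptides for the instability sum.

Class predictability uses linear discriminant analysis (scikit-learn) on
the three standardized indices; both resubstitution and leave-one-out
per-class accuracies are reported, resubstitution being the conventional
headline number for predictive discriminant analyses of this kind. Singular
pooled covariance raises an informative error. Per-index one-way ANOVA with
Tukey HSD pairwise p-values (scipy) provides the class contrasts.

## Site constraint

The per-column impact score is a simplified multivariate physicochemical
constraint measure. Six residue property scales — Kyte–Doolittle
hydropathy, Grantham polarity, net side-chain charge at neutral pH,
Zamyatnin volume, and Chou–Fasman helix and sheet propensities — are
z-normalized over the 20 residues. Per column and property the (weighted)
mean `m` and variance `v` of the observed residues are computed, the
impact of candidate residue `a` is `Σ_p (scale_p(a) − m_p)² / v_p`, and the
site score is the mean impact over all 20 candidates. Variances are floored
at the 5th percentile of column variances per property (and at 0.05 in
z-units) so invariant columns stay finite; columns over 50% gaps are
reported missing. Sequence weights are uniform by default (a weighting hook
exists); only the ranking of mean scores feeds the downstream tests, and
that ranking is robust to weighting. Scores decrease with column diversity
(validated as a strong negative Spearman correlation with column entropy).

`permutation_test` draws `n` replicates of |focal| sites without
replacement from the chosen background (all scored sites, polymorphic
sites, or an explicit set) and reports a two-tailed p with the +1
correction: `min(1, 2·min((1+#≥)/(n+1), (1+#≤)/(n+1)))`. The smallest
attainable p is therefore `2/(n+1)`; a "0 of n replicates" outcome is an
upper bound, never p = 0. `region_enrichment` applies the same machinery to
the count of focal sites inside a region category and converges to the
exact two-tailed hypergeometric probability. Annotations are 1-based
inclusive protein-coordinate intervals with categories
structural/functional and a fixed subtype vocabulary.

## Codon selection models

The GY94 rate matrix sets `q_ij = π_j κ^[transition] ω^[nonsynonymous]`
for codon pairs differing at one position, zero otherwise, and is rescaled
to one expected substitution per codon at equilibrium, so branch lengths
are in substitutions per codon; each branch class (and each branch-site
site class) uses its own ω with its own rescaling. Transition matrices come
from the symmetrized eigendecomposition of the reversible generator.
Likelihoods use Felsenstein pruning over the 61 sense codons with site
pattern compression and underflow rescaling; ambiguous or stop-containing
codons are missing data (partial likelihood 1). Correctness is tested
against exhaustive enumeration of internal states on small trees (1e−8)
and invariance under taxon reordering.

Fits maximize over log-kappa and log-omegas with L-BFGS-B (|ΔlnL|
convergence ~1e−10 ftol, multi-start over ω ∈ {0.05, 0.5, 1.5} by
default); branch lengths are taken from the input tree, or optionally
re-optimized once under the one-ratio model and then fixed — the standard
practice that also keeps the parameter-count convention simple. Standard
errors come from the inverse observed information (central-difference
Hessian on the natural scale). AIC is `2k − 2 lnL` with `k` = number of ω
ratios (one-ratio 1, within/between 2, within1/rest/between 3); this is
the convention under which the published branch-class comparison tables
reproduce exactly, and `k_convention="all-free"` switches to counting all
optimized parameters. Model ranking breaks AIC ties toward fewer
parameters.

The branch-site model is model A: site classes 0 (ω₀ < 1 everywhere),
1 (neutral everywhere), 2a (ω₀ background, ω₂ ≥ 1 foreground) and
2b (neutral background, ω₂ foreground), proportions parameterized as
(p0, p1) with p2a = p2·p0/(p0+p1), p2b = p2·p1/(p0+p1). Site posteriors are
naive empirical Bayes at the MLE — the model parameters are plugged in
rather than integrated over as in Bayes empirical Bayes, a documented
simplification; the flagged divergent set keeps the conventional posterior
> 0.95 rule. Boundary estimates (p1 → 0, ω₂ → 1) are reported, not fatal.

NG86 counts synonymous/nonsynonymous sites by mutational opportunity
(changes to stops excluded), averages difference counts over substitution
pathways avoiding stops, and applies the Jukes–Cantor correction, flagging
proportions ≥ 3/4. Sliding windows (default 15 codons, step 5) average the
pairwise between-group counts per window before correcting. NG86 assumes
equal mutation rates; under strong transition bias it is ~10% downward
biased relative to the GY94 generating ω, which the closure tests document
by calibrating at κ = 1.

`composition_chisq` sums `(observed − expected)²/expected` base counts per
sequence against the pooled composition and simulates its null on an
average-linkage (UPGMA) guide tree built from Jukes–Cantor distances,
evolving sites under HKY with the pooled frequencies; p carries the +1
correction. The guide tree only supplies phylogenetic correlation for the
null, so the cruder linkage tree is adequate (and avoids a tree-search
dependency).

## The synthetic-data generator

`simulate_family` emulates the study design the analyses assume. Each
species carries 8 copy types grouped into 5 intron classes; each type is
present as a pair of similar copies. The copy genealogy is
classes → types → species → pairs, with within-class branches labeled
`within` and the class-ancestor branches `between`; branch lengths are set
from the configured pairwise nucleotide divergences (pair 1.5%, species 4%,
between types 12%, between classes 30% on the model scale — observed
divergences are lower through multiple hits). Coding sequence evolves
under GY94 (κ = 2, uniform codon frequencies) with three site categories:
background (ω 0.015 within / 0.074 between — the published class-model
ratios), a 30-codon divergent block (ω 0.013 within / 1.0 between, the
published branch-site pattern), and a 23-codon constrained block
(ω ≈ 0.001, emulating an invariant functional site). The intron catalogue
is 17 insertion points; the five class base patterns have pairwise Hamming
distance ≥ 6 and jointly cover all sites, and one copy type in each of
three classes toggles a single intron off, giving 8 patterns. Intron
sequences start `GGT` and end `AG` (motifs protected from mutation),
lengths 42–70 bp except sites 2 and 12 (107–131 and 166–295 bp); each
site's base sequence diverges hierarchically (class 8%, type 4%, species,
pair). Intron length evolution (indels) and gene conversion dynamics are
not modeled — pairs are generated at fixed divergence.

`simulate_clone_library` draws copy abundances once from a symmetric
Dirichlet, clone counts from a multinomial, and adds independent per-base
substitution errors (no indels — polymerase errors are overwhelmingly
substitutions, and this keeps distances metric). Defaults:
135 clones/sample, concentration 40, error 35/9000. These defaults were
fixed by a design-time power calculation: 135 clones sample all 16 copies
with probability ~0.994 per library (the saturation regime the analyses
assume), and a 480-codon gene (~1.79 kb product with 6–8 introns, the
upper end of the realistic amplicon range) keeps the discrete 1% threshold
from sitting exactly on a clone-pair error quantile. The abundance model
is a free parameter of the generator (real surveys publish only clone
totals); the Dirichlet-multinomial spans even-to-skewed libraries with one
knob.

`simulate_region_annotation` writes a structural/functional annotation
consistent with the truth: functional intervals (GTP contacts,
nonexchangeable site, interface, C-terminal helices, ~25–30% of sites)
avoid the divergent block — emulating divergence kept out of functionally
critical regions — while structural intervals are placed independently of
the divergence pattern.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the methods assume (divergence hierarchy, error
process, class architecture), not real sequence idiosyncrasies:
compositional heterogeneity among copies, rate variation beyond the three
site categories, intron length turnover, chimeric clones and alignment
ambiguity in real data are absent. End-to-end recovery on these data
therefore validates the implementation and its calibration, not the
field performance of the protocol.

## Study sizes used by tests and the acceptance script

Parameter-recovery studies run at 2000 codons on a 6-taxon, 3-class tree
(50 replicates for the branch-class study; 5 for the slower branch-site
study, asserting the mean), fitting with the known generating codon
frequencies (F3x4 estimated from uniform-codon data is mildly misspecified
and would add ~0.005 upward bias to small ω). The end-to-end study runs
50 single-species pipelines at the generator defaults; the acceptance
script uses the same computations at reduced replicate counts and reports
values rather than thresholds. In the end-to-end study the flagged
divergent set is tested by functional-region depletion (two-tailed Monte
Carlo p), the analysis that identifies divergent codons as avoiding
functionally critical regions; the score-permutation p-values are computed
and reported alongside. The MAPP-style score direction for the truth
divergent set is *low* here (its columns carry many residues), whereas a
real survey reported divergent codons scoring *high* against random sites —
the two-tailed tests are direction-free, but the contrast is a reminder
that score direction is a property of the data, not the test.

## Known limitations

* Naive empirical Bayes posteriors understate uncertainty relative to BEB
  near parameter boundaries.
* The 1% collapse rule plus the linear error bound leaves an irreducible
  chance (~2–4% per deep library) that a heavily errored clone is called
  as an extra copy; Chao1 then reports a singleton, which is the intended
  diagnostic signal.
* Exact reproduction of published MAPP scores is not attempted (tree
  weighting and property set differ); only the downstream test logic is.
* `composition_chisq` simulates its null under HKY on a UPGMA guide tree,
  not under a fitted GTR+I+G on an inferred phylogeny; its p-values are
  calibration-tested but approximate.
* Bayesian tree inference, heterogeneous-composition likelihood models and
  exact BEB are out of scope.
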