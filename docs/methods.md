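# Methods

This note documents the models, estimators, numerical choices and study
conditions behind `evomap`, and what the package's tests do and do not
establish about real data.

## Coordinate system and structural model

Alignments are fixed-width (74 columns) structural alignments of tRNA genes
over {A, C, G, U, -}. Columns are named by Sprinzl coordinates — the
standardized numbering of the consensus tRNA cloverleaf — with two
deliberate properties:

* The D-loop insertion **20A** is kept as its own coordinate, and every
  later label is shifted up by one; consequently the label **"21" does not
  occur** and the final (discriminator-adjacent) coordinate is 74. This is
  the single numbering under which the nine structural components below
  tile all 74 columns exactly once while the variable-arm window is 45–49.
* Only variable-arm coordinates 45–49 are retained; the long variable arms
  of serine/leucine tRNAs are assumed excised before alignment.

Stem pairing follows the standard convention: acceptor 1:72 … 7:66, D-stem
10:25 … 13:22, anticodon stem 27:43 … 31:39, T-stem 49:65 … 53:61. Two
nine-component partitions of the sites are provided:

* **rate partitions** (default for rate analyses): acceptor 1–7 & 67–73,
  D-stem 10–13 & 23–26, D-loop 14–22 (i.e. 14…20, 20A, 22), anticodon stem
  28–32 & 40–44, anticodon loop 33–39, variable arm 45–49, T-stem 50–54 &
  62–66, T-loop 55–61, other {8, 9, 27, 74};
* **pairing-aligned partitions**, in which the four stems consist of
  exactly the paired sites and loops absorb the remainder. This variant is
  used when stems are modelled as 16-state doublets, so charsets and pair
  statements coincide, and it is the scheme under which "every paired site
  lies in a stem" holds exactly.

The two schemes differ by one coordinate at most component boundaries; the
package treats the choice as a configuration switch rather than resolving
it by fiat, because the two conventions circulate in the field's
literature.

Gene filtering retains genes with covariance-model (COVE) scores of **at
least** 50 bits (a gene scoring exactly 50.0 is kept), drops genes of
indeterminate function ("?") and selenocysteine tRNAs ("Z") by default, and
drops genes flagged for anticodon-shift substitutions or as pseudogenes.
Ambiguity codes and any non-ACGU symbol are treated as gaps and logged.

## The functional-information statistic

For feature state *x* at site (or site pair) *l*,

I(l, x) = max(0, H(Y) − Ĥ(Y | X_l = x)),

with H(Y) the plug-in entropy of the gene-frequency distribution over
functional classes and Ĥ the estimated class entropy among the n genes
carrying *x*. Genes gapped at any involved column are excluded from that
feature table and tallied as missing. The clip at zero exists because the
Bayesian conditional estimate can exceed H(Y); logo stack heights cannot be
negative.

**Estimator dispatch.** Features carried by n ≥ 2 genes use the NSB
estimator; singletons use the exact small-sample estimator. Both are
exposed directly, and a pure plug-in mode is available for sensitivity
analysis and for oracle tests.

**NSB.** A symmetric Dirichlet prior with concentration β on k classes
induces a sharply concentrated prior on entropy; NSB integrates over β with
the hyperprior that is flat on the prior expected entropy
ξ(β) = ψ(kβ+1) − ψ(β+1). We integrate over ξ ∈ (0, log k) by composite
16-point Gauss–Legendre quadrature, doubling the panel count (from 8, up to
256) until the posterior mean is stable to a relative 10⁻⁶. The integrand
uses the standard Dirichlet posterior moments of H and H² (Wolpert–Wolf),
evaluated in log space for stability; the β(ξ) inversion is a vectorized
bisection whose grid is cached per (k, panels), since it is independent of
the data. The posterior standard deviation is returned alongside the mean.

**Exact small-sample estimator.** For a feature observed n times, the
estimate is the plug-in entropy plus the exact expected sampling deficit
H(bg) − E_n[H_plugin], where the expectation is over multinomial samples of
size n from the background class composition, computed by exact enumeration
over all compositions of n into k parts. For n = 1 the plug-in term is zero
and the estimate equals the background entropy: a singleton says nothing
about class identity, so its information is zero. When the composition
count exceeds 2·10⁵ the first-order deficit (k−1)/(2n ln 2) is used instead
(with a logged warning); the deficit vanishes as n grows, so the estimator
is consistent.

**Letter heights.** The statistic fixes a stack's total height; the split
across classes is a convention. Each class receives weight
max(0, log₂(f(y|x)/f(y))) and heights are the weights renormalized to sum
to I — the normalized log-odds rule used by function-logo software. Classes
at or below background frequency get zero height; if no class is
over-represented (possible when I > 0 comes purely from estimator
variance), all heights are zero.

## Permutation significance and multiple testing

For each (site, state) feature carried by n genes, the class labels of
those genes are re-drawn without replacement from the complete class-label
pool of the alignment, B times, and

p = (1 + #{I_perm ≥ I_obs}) / (B + 1),

so p is floored at 1/(B+1) and is a valid (slightly conservative)
permutation p-value. Labels are permuted per feature; the draw order is
fixed (sites, then states, sorted), so results are deterministic given the
seed, which is mandatory. The default B is 9999 in the CLI.

By default p-values are computed for paired-site features only, which form
one Benjamini–Hochberg family (q-values via the step-up rule with
monotonicity enforcement, delegated to statsmodels); single-site p-values
are available behind a flag, and Bonferroni family-wise control is offered
as an alternative. `significant_cifs` retains entries with q ≤ the chosen
FDR (5% by default).

Because entropy estimates depend on the count vector only through its
multiset of counts, permutation replicates are memoized on sorted counts;
this makes NSB-based permutation affordable at small n and plug-in-based
permutation fast at any n.

## Concatenated ortholog alignments and subset optimization

An ortholog set contributes to the concatenation for a species subset iff
its species coverage is a **superset** of the subset; surplus species are
dropped so rows stay rectangular. Blocks are ordered by set id. Alignment
statistics: gap-free sites have no gap in any row; variable sites are
gap-free with ≥ 2 states; parsimoniously informative sites are gap-free
with ≥ 2 states each in ≥ 2 rows; the mean pairwise difference is the
average over row pairs of the per-site difference fraction on gap-free
columns (gap handling is a package decision — the statistic's source names
it without specifying gaps). Subsets are ranked lexicographically by
(gap-free sites, set count, PI sites, mean pairwise difference),
descending; the tie-break order is configurable because a clearly dominant
subset renders it moot in the motivating use case.

**NEXUS output** (MrBayes 3.2 dialect) writes the data matrix, one charset
per structural component (scheme `structural`, exactly nine) or per Sprinzl
coordinate (scheme `per_site`), GTR+I throughout by default (GTR+I+Γ via a
flag, results being insensitive to the choice in the motivating analyses),
or Doublet(GTR)+I on stems with nucleotide GTR+I on loops (scheme switches
to the pairing-aligned partitions and emits the pair statement). The
species-tree topology is fixed: topology moves get zero proposal
probability. Rate multipliers are reported with `ratemult = scaled`, i.e.
scaled to mean 1.0 substitutions per site or site-pair across partitions.
MCMC defaults: 2 runs, 4×10⁶ generations, sampling every 500, 25% burn-in —
all flags.

**Posterior summarization** reads `.p`-style tab-separated sample tables
(tolerating a leading `[ID: …]` line), discards the first burn-in fraction
of each file, pools runs (headers must match), and reports per-multiplier
median, IQR and central 95% credible interval.

## Enrichment statistics

The ion-pocket test reports the hypergeometric **point** probability
C(K,k)·C(N−K,n−k)/C(N,n) with exact integer binomials (Fraction
arithmetic), matching the convention of reporting the probability of the
observed overlap itself; an upper-tail variant is provided. The chi-square
test is Pearson's without continuity correction (scipy), df = (r−1)(c−1);
degenerate tables (zero marginals) are rejected.

## Synthetic-data generator

The generator emulates the statistical structure of a re-annotated insect
tRNA gene complement: by default 22 functional classes (20 amino acids,
initiator "X", selenocysteine "Z") × 13 gene copies = 286 genes, 74
columns, and an 11-species roster for ortholog sets — the scale at which
the real analyses operate, small enough for seconds-scale tests.

Genes of a class derive from a class consensus, itself a divergence of a
shared global consensus; background substitutions and gaps are applied per
gene. Planted CIFs impose a state on target classes with one penetrance
draw per gene per planting (pair states are imposed jointly). Two
constructional invariants matter for interpretation:

* the shared consensus never carries a planted state, and the avoidance is
  identical across classes — otherwise planted columns would acquire
  class-specific consensus bases and the plantings would not be the only
  class signal;
* a planting at full penetrance necessarily **induces one complementary
  true feature** per planted site: the consensus state there is carried by
  every gene except the target classes and genuinely informs against them.
  Recovery studies therefore count planted states and their complements as
  ground truth.

Ortholog-set simulation gives each species a presence probability per set;
the defaults grade four species down (0.55, 0.45, 0.35 and 0.05 — the last
a very-low-coverage analogue), so the subset excluding exactly those four
dominates every ranking criterion and subsets excluding the low-coverage
species concatenate far more sets.

What the generator does **not** emulate: phylogenetic correlation
(sequences are not evolved down a tree), base modification, realistic
covariation between stems' partners beyond planted pairs, alignment error,
or COVE-score/structure dependence. Passing recovery tests therefore shows
the statistical machinery is correct and calibrated under exchangeable
noise, not that real fly genomes meet those assumptions.

## Calibration studies

Two studies (in `evomap.validation`) are run by the test suite and the
reproduction script. Both use the plug-in estimator inside the permutation
loop: permutation validity is estimator-independent, and the plug-in's
small-sample bias affects observed and permuted statistics identically,
while keeping 10⁵–10⁶ replicate evaluations tractable.

* **Planted recovery**: 22 classes × 8 copies, class divergence 0,
  substitution rate 0.02, four planted paired-site features (two pairs,
  two mis-pairs) at penetrance 1.0 in one or two classes each; all 21 stem
  pairs tested with B = 999 permutations, BH FDR 5%; 20 independent data
  sets per study. Expected and observed: 100% sensitivity, mean empirical
  false-discovery proportion ≤ 5% (0 in practice).
* **Null calibration**: alignments whose sites are i.i.d. draws from the
  base composition for every gene, so every feature is null and its
  carrier set exchangeable; 500 single-site features with ≥ 5 carriers,
  B = 1000. The KS distance of the pooled p-values from uniform behaves
  like that of genuinely uniform draws (median ≈ 0.83/√500 ≈ 0.037);
  values near 0.05 can occur at individual seeds by sampling variation
  alone, and features below ~5 carriers are excluded precisely because
  their permutation distribution is too discrete for the comparison to be
  meaningful.

## Numerical and degenerate-case choices

* Entropy is in bits everywhere (log base 2).
* Information is clipped at 0; heights sum to I exactly (to 10⁻⁹) unless no
  class is over-represented.
* Permutation p-values are floored at 1/(B+1) and never 0; BH inputs must
  lie in (0, 1].
* Empty alignments filter to empty with a warning rather than erroring;
  empty feature tables yield no entries; rendering an empty CIF table is an
  error.
* Subset enumeration is ordered by decreasing size then combination order,
  so output is reproducible without sorting.
* Exact binomials avoid overflow at any N the pocket test will see.

## Known limitations

* The NSB integral assumes a symmetric Dirichlet family; strongly
  non-exchangeable class priors are out of scope.
* The exact small-sample estimator's enumeration is exponential in n; it is
  intended for singletons and very small n, with a logged first-order
  fallback elsewhere.
* The NEXUS emitter targets MrBayes 3.2 syntax but the package never runs
  MrBayes; files are validated structurally (charset coverage, matrix
  round-trip), not by execution.
* Cross-taxon comparison flags top-class switches only; it does not model
  gains/losses on a tree or compute ancestral states.
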