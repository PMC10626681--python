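# Methods

This note records the models, algorithmic commitments and numerical choices
behind `harmobench`, in the order the pipeline runs them.

## Codon usage tables and derived measures

The canonical internal scale is frequency per thousand codons (the Kazusa
convention); counts are optional and, when present, must be consistent with
the frequencies within print rounding (±0.05 per thousand). Family-relative
measures are always derived on demand, never stored as primary, because the
%MinMax profile needs absolute frequencies while the recoders need
family-relative ones:

- family fraction `f_j / Σ_family f`,
- RSCU `f_j / mean_family f`,
- relative adaptiveness `w_j = f_j / max_family f`,
- rank (competition rank, 1 = most used; ties share the lower rank) and a
  fully tie-broken ordinal (descending frequency, then lexicographic) used
  wherever reproducibility requires a total order.

A synonymous family with zero total usage degrades to uniform measures
(fraction 1/n, RSCU 1, w 1) with a logged warning rather than an error:
sparse tables for poorly sequenced organisms are legal inputs, and a hard
failure would make them unusable.

## Windowed usage measures

%MinMax uses a sliding window of 18 codons for evaluation (17 inside the
descent recoder), step one codon, non-circular. Windows made entirely of
single-codon families (or degenerate tables) have a zero denominator; the
statistic is defined as 0 there, since such windows carry no usage-bias
signal. Genes shorter than the window yield a single whole-gene window, so
every gene has a profile. The statistic is invariant under uniform
rescaling of the table and confined to [−100, 100] (clipped against float
overshoot at the closed-form extremes).

The geometric-mean mode is computed on family fractions (floored at 1e−6
before taking logs) rather than on raw frequencies: fractions make the mode
scale-free, mirroring %MinMax's scale invariance, and put its values in
(0, 1]. Whether per-thousand frequencies or fractions are "the" right scale
for this mode is underdetermined; the choice is documented here and
localized in one function.

## Harmonization strategies

All recoders preserve the translation exactly. Internal stop codons are
rejected as input errors; the terminal stop is excluded from recoding by
default (a flag includes the 3-codon stop family). Windows containing the
stop codon still enter the profiles, so the exclusion is consistent on both
sides of every comparison.

**Pointwise measure matching.** Each position independently takes the
target-host synonymous codon minimizing |measure(candidate, target) −
measure(original, source)|. The measure selects the emulated strategy:
RSCU, relative adaptiveness, or family fraction. At tolerance 0 ties keep
the original codon (making self-harmonization an exact no-op), then break
lexicographically. Note that at tolerance 0 the RSCU and family-fraction
variants are *identical by construction*: within a family of size n,
RSCU = n × fraction, so the argmins coincide; the two labels only diverge
when the tolerance pool is active. For tolerance t > 0 the candidate pool
is every synonymous codon within `d_min + t (d_max − d_min)` of the best
distance, sampled with probability ∝ 1/(1e−9 + |Δmeasure|), positions
visited in seeded random order. The tolerance-to-probability law is a
committed design choice — inverse-distance weighting is the simplest law
that makes closer codons proportionally likelier — and the benchmark's
default (t = 0) does not depend on it.

**Sliding-window descent.** The target is the original gene's windowed
profile under the source table; candidates are scored under the target
table; the objective ("net deviation") is the absolute-difference sum over
windows. Absolute rather than squared differences are used because the
termination criterion is phrased in terms of decreasing net deviation; the
objective function is injectable for sensitivity checks. Descent starts
from the rank-matched (ordinal-matched) recoding and applies, per
iteration, the single synonymous substitution with the largest objective
decrease (steepest descent, not first-improvement — deterministic and
seed-free), stopping when no substitution decreases the objective by more
than 1e−7. Because synonymous substitution never changes a position's
family, the per-window family statistics are constants and a move touches
at most W windows, so candidate deltas are maintained incrementally and a
full run on a 600-codon gene takes well under a second. Multiple solutions
(`n_solutions > 1`) restart from seeded random synonymous sequences and
collect distinct local optima; the lowest-objective one is returned.

## Evaluation

ΔMinMax is harmonized-under-target-CUT minus original-under-source-CUT,
per window; per-gene RMSE is against a zero target. For RMSE_codons, the
per-gene occurrence ORI%/HARM% is the codon's count divided by its family's
count *within that gene* (the per-gene quantities are what the over-genes
sum runs over); a codon whose family is absent from a gene is undefined
for that gene and skipped with n reduced — imputing 0 would manufacture
signal where none exists. Codons whose family occurs in no gene report 0.
The per-combination mean RMSE_codons is reported both over all 64 codons
(single-codon families contributing their structural zeros) and excluding
ATG/TGG, since either convention is defensible for a summary row.

The special tool name `identity` evaluates the unmodified gene against its
own source table and must produce all-zero RMSE and RMSE_codons — the
pipeline's end-to-end null, exercised in the tests.

## mRNA structure covariate

"Involved in secondary structure" is operationalized as "base-paired".
The default predictor is Nussinov-style base-pair maximization (AU/GC/GU
pairs, minimum hairpin loop 3 nt) with a deterministic traceback (the
rightmost base of an interval pairs whenever pairing attains the optimum,
smallest-index partner first). Base-pair maximization is a structural
upper-bound model, not a thermodynamic one: it overpredicts pairing
relative to minimum-free-energy folds, so absolute %mRNA values are higher
than RNAfold's, while the *ordering* of genes by structure content — what
the covariate feeds the regression — is preserved in practice. Users who
need thermodynamic fidelity can supply RNAfold dot-bracket strings, which
flow through the identical %mRNA computation. Folding always applies to
the original gene, never the harmonized variant: the covariate describes
the input, not the design. %mRNA per window is the paired fraction of the
window's nucleotides; the gene value is the mean over windows.

## Statistical comparison

Evaluation records are repeated measures within genes, so tools are
compared with GEE: Gaussian family, identity link, exchangeable working
correlation, genes as clusters. Continuous covariates (mean GC, mean
%mRNA) enter linearly by default; the formula is a configuration knob, so
quadratic terms can be added where curvature is suspected. Factors and
interaction blocks are tested jointly with Wald tests on the coefficients.

With only tens of clusters the classical sandwich chi-square Wald test is
anti-conservative (measured empirical size ≈ 0.14 at nominal 0.05 over 200
null simulations with 30 genes). The package default therefore uses the
bias-reduced (Mancl–DeRouen) sandwich together with a scaled F reference
with K − p denominator degrees of freedom (K clusters, p coefficients),
the standard few-cluster remedy; its measured size is ≈ 0.03 and its power
against a tool effect of twice the residual SD is ≈ 1.0 under the same
simulation. Both corrections vanish asymptotically, and
`small_sample=False` restores the classical chi-square test. A constant
response makes the Gaussian GEE degenerate (zero scale), so `fit_gee`
falls back to ordinary least squares there, which yields the identical
intercept-only solution.

Interaction fits are refused when the cluster count is below five times
the coefficient count (override flag available): too few genes cannot
support interaction estimates without overfitting, and the refusal is
logged rather than silent. Tool rankings are ascending mean-RMSE orderings
(overall and per host), with ties reported explicitly and an optional
gene-level bootstrap attaching the frequency with which each tool holds
its observed rank.

## Synthetic scenarios

The generator emulates the statistical structure the benchmark assumes,
not any particular organism:

- **Tables**: per family, fractions ~ Dirichlet(α · tilt) with
  tilt = exp(β) per G/C third base. α = 3 by default — strong enough bias
  that harmonization has something to preserve, weak enough that no codon
  is effectively absent. Host presets differ only in β: +0.3
  (enteric-bacterium-like), −0.8 (budding-yeast-like AT-leaning), +2.5
  (streptomycete-like GC-rich). Amino-acid weights default to the average
  UniProtKB proteome composition, with one stop per ~330 codons.
- **Genes**: 100–600 codons, in-frame, ATG start, single terminal stop.
  The amino-acid distribution is exponentially tilted (bisection on the
  tilt) so the target GC is reachable, then seeded synonymous swaps tune
  whole-gene GC to ±0.02 of target; unreachable targets report the best
  achieved GC, never silently. Each gene's source table uses a GC-matched
  β (6 × (target − 0.5)), mirroring how genomic GC drives codon bias.
- **Default design**: 27 genes with GC targets spanning 0.30–0.80,
  alternating oxidoreductase/transferase-style class labels (EC1/EC2), two
  hosts — 270 evaluation records. **Validation design**: 8 genes — two
  high-GC, two low-GC, and four with embedded inverted repeats of 0/12/24/36
  nt stem length to grade secondary-structure content monotonically under
  the internal fold.

What the generator does *not* emulate: real genes' domain structure,
codon-pair and dinucleotide effects, genuinely thermodynamic RNA folding,
and database-versioned CUTs. Passing tests therefore demonstrate the
correctness and calibration of the machinery on data with the assumed
statistical structure, not the field performance of any real tool on real
genomes. Gene lengths of 100–600 codons are a desk-scale assumption.

## Determinism and problem sizes

Every stage derives its seed from the master seed via CRC-tagged
`SeedSequence` children (stable across processes), so a rerun with the same
configuration is byte-identical, including CSV float formatting (shortest
round-trip `repr`). The default test and benchmark sizes — 27-gene
scenarios, 200-replicate statistical calibrations, exhaustive oracles up to
12 nt / 12 codons — were chosen so the whole suite exercises every claim at
full fidelity in a few minutes on a single CPU.

## Known limitations

- The tolerance→probability law of the stochastic pointwise recoder and
  the absolute-difference net deviation of the descent recoder are
  committed readings of underdetermined descriptions; both are isolated
  behind task parameters.
- The descent recoder finds a local optimum of a non-convex objective;
  restarts probe alternatives but no global-optimality claim is made.
- %mRNA from base-pair maximization is an upper-bound structure model (see
  above).
- CUT comparisons use per-thousand frequencies throughout; for %MinMax the
  choice is irrelevant (scale invariance), for the geometric-mean mode the
  family-fraction scale is a documented choice.
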