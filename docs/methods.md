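# Methods

## Data model

A study is a continuous genes × samples matrix in which every gene carries
one of three roles (miRNA, TF, mRNA) and every sample a condition label
(two conditions throughout). Regulatory hypotheses are typed directed
edges limited to the five admissible combinations — miRNA→mRNA, miRNA→TF,
TF→miRNA, TF→TF, TF→mRNA — so mRNAs are always sinks. This constraint is
enforced at every boundary: file ingest, prior construction, learning
output, and network randomisation.

## Filtering and discretisation

Differential expression uses a two-sided Welch two-sample *t*-test per
gene with Benjamini–Hochberg correction applied separately within each
role, because the selection cut-offs are role-specific (strict
adjusted *p* < 0.01 for miRNAs, < 0.1 for TFs and mRNAs, all
configurable). Welch's test is a deliberate, documented stand-in for a
moderated-*t* pipeline; the learning stages downstream are agnostic to
how the gene list was produced, and `de_thresholds=None` skips the filter
entirely for data that is already gene-filtered. Genes with zero overall
variance are dropped with a warning (their statistic is undefined); genes
constant within both groups score *p* = 1 when the group means agree and
*p* = 0 otherwise.

Discretisation is per sample (per array): a value strictly above the
sample's median becomes 1 (up-regulation), anything else 0. Ties at the
median therefore map to 0, making the rule deterministic and invariant
under strictly monotone per-sample transforms — the property that lets
matrices from different platforms be combined. Data that is already 0/1
is used as-is rather than re-thresholded, since re-applying the median
rule to binary columns would zero every column whose median is 1.

## Scoring

The BDe family score is computed in natural-log space from the log-Gamma
function; no raw Γ is ever evaluated (underflow starts around 50
samples). Hyperparameters follow the BDeu rule a_ijk = α/(r_i·q_i) with
equivalent sample size α = 1.0 by default: the score is then
likelihood-equivalent, so Markov-equivalent structures score identically
(verified numerically to 1e−9). The structure prior is uniform and
dropped. With zero samples the score is 0, the log of an empty product.
Binary variables are assumed (r_i = 2, q_i = 2^p); sufficient statistics
are accumulated by radix-indexing the parent columns, so one family
evaluation is O(S + 2^p).

## Structure learning

Candidates are generated by removing prior edges. Because the score
decomposes over child-with-parents families, the decision for each edge
is taken per child: all 2^p subsets of the child's candidate parents are
scored, and the edge is present iff the arithmetic mean of the log-scores
over the subsets containing its source strictly exceeds the mean over the
complement, with ties resolved to absent (conservative). The
regulator-centric enumeration over whole candidate structures
(`enumerate_candidate_structures`) reaches identical decisions — all
other families' terms appear on both sides of the comparison and cancel —
which the suite asserts; the per-child route merely bounds the exponent
by the in-degree. Families larger than 16 candidate parents raise an
error rather than silently exploding: the exhaustive search is feasible
only because target information keeps in-degrees small, and the cap makes
that contract explicit.

## Bootstrap confidence and integration

Each of the C conditions is resampled with replacement n times (default
n = 100) and the per-condition learner re-run; learning an edge in one
run is a Bernoulli event with null probability ½ (an edge is either
present or absent, with no preference). Total support Q over the C·n runs
is Binomial(C·n, ½) under the null; the upper-tail p-value is computed by
exact integer summation of binomial coefficients, so it is the correctly
rounded double of the exact rational tail (trials are small; no normal
approximation). Edges with p strictly below 0.05 (configurable) enter the
global network with their (Q, trials, p) attached. Conditions contribute
equally regardless of their sample sizes, as the binomial model implies.
One RNG stream per (bootstrap, condition) pair is derived from the master
seed, so counts do not depend on the edge set or iteration order and full
runs are bit-reproducible. The integrated network may contain cycles
(e.g. mutual TF–miRNA repression); it is a directed graph, not a Bayesian
network.

## Interplay and motifs

The interplay subnetwork keeps edges whose two endpoints are both
regulators, in either direction. FFL instances are ordered triples
(A, B, C) with A→B, B→C, A→C and at least two regulator nodes; in
networks produced by this pipeline mRNAs have out-degree 0, so A and B
are always regulators and the filter only matters for externally supplied
graphs (the suite asserts this). Significance uses edge switching:
swap_factor × |edges| attempted swaps (default 10), with mutual dyads
swapped only against mutual dyads and single edges only against single
edges, so per-node in/out degrees *and* the 2-node subgraph census are
preserved. Proposed swaps creating self-loops, duplicates, or
role-forbidden edge types are rejected; the role-feasibility rejection is
deliberately stricter than plain degree preservation so that null
networks remain biologically typed. The empirical p uses add-one
smoothing, (1 + #{null ≥ real})/(1 + n_random); the z-score is omitted
when the null counts have zero spread. Defaults: n_random = 1000, or 100
in the CLI's `--quick` mode.

## Synthetic studies

The generator plants a typed random network (defaults: K = 10 miRNAs,
I = 10 TFs, J = 30 mRNAs, 10 edges of each of the five types), then draws
two-condition expression. Parentless genes are Bernoulli(½); a child is 1
with probability logistic(b0 + Σ_p sign_c(p)·w·x_p), weight w = 3 by
default. miRNA-sourced edges carry sign −1 (repression), TF edges +1, and
a mix-regulation fraction (default 0.2) flips sign between the two
conditions — the situation condition-wise splitting exists for. The
baseline is centred, b0 = −(w/2)·Σ_p mean_c sign_c(p), so a lone positive
parent with w = 4 gives b0 = −2 and conditional probabilities
logistic(±2) ≈ 0.88/0.12; without centring, repressed children are nearly
constant and carry no signal. Genes are drawn in topological order of the
strongly connected components so every child outside a feedback core sees
its parents' final values; cyclic cores are initialised at the marginal
and settled with a single extra pass, which keeps mutual regulation
dependent while remaining a one-shot sampler rather than a full Gibbs
chain. Continuous mode emits Normal(0, σ) / Normal(2, σ) around the
latent state (σ = 0.5 default). Target lists mix the true edges with
type-valid decoys at a requested decoy fraction (default 0.5), imitating
the high false-discovery rate of sequence-based target prediction; an
explicit decoy count supports pure-noise null studies with no true edges.

What the generator does *not* emulate: continuous dose–response
regulation, measurement batch effects, probe-level noise, unbalanced
condition sizes, and marginal condition shifts in root genes (roots are
Bernoulli(½) in both conditions, so the synthetic data deliberately
carries no differential-expression signal — recovery runs skip the DE
filter). Passing recovery tests therefore demonstrates the learner and
confidence model, not the DE stage, whose behaviour is tested separately
on constructed two-group data.

## Problem sizes and numerical choices

The suite and the acceptance script use 5 master seeds, 60+60 (recovery)
or 30+30 (noise) samples, 50 bootstraps, and 100–500 null randomisations;
these sizes give stable averages while keeping a full run in the tens of
seconds. Exhaustive BDe-oracle checks cover every joint column pattern on
a graded grid (up to 6 samples with no parents, shrinking to 2 samples
with 3 parents) plus seeded random families at the full sizes; the
sequential Dirichlet-multinomial predictive product is the independent
oracle, agreed to 1e−10 in log space. Binomial tails are compared against
an independent survival-function implementation for every (Q, trials ≤
200). Score ties decide edges to absent; the averaging operation uses the
arithmetic mean of log-scores.

## Known limitations

- Exactly two conditions are supported by the DE stage (the learning and
  integration stages accept any C ≥ 1).
- Variables are binary after discretisation; multi-level expression
  states are out of scope.
- The motif catalogue is the 3-node FFL only.
- The bootstrap null probability ½ is an assumption, not an estimate; with
  very weak priors it is conservative, with dense priors anti-conservative.
- Probe-to-gene collapsing is not performed: each input row is one node.
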