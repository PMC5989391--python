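# Methods

This note documents the statistical model behind `methnet`, the
parameters that matter, the numerical choices, what the synthetic
benchmark does and does not establish, and the design decisions taken
where more than one reasonable construction existed.

## Information estimators

All variables are treated as continuous and jointly Gaussian for the
purpose of estimation.  For a d-dimensional system with sample
covariance C (ddof = 1), the differential entropy is
H = (d/2) ln(2πe) + ½ ln|C| nats, giving

- MI:  I(X,Y) = ½ ln(|C(X)|·|C(Y)| / |C(X,Y)|)
- CMI: I(X,Y|Z) = ½ ln(|C(X,Z)|·|C(Y,Z)| / (|C(Z)|·|C(X,Y,Z)|))

On bivariate-normal data these reduce to −½ ln(1−r²) (sample Pearson r)
and −½ ln(1−ρ²) (sample partial correlation), identities the tests use
as independent oracles.  Methylation beta values are bounded in [0,1];
the Gaussian estimator is applied to them directly, which is adequate
because the logistic-scale signals underlying betas are near-linear over
the bulk of the range.  Values are computed in nats and reported in bits
(÷ ln 2) wherever the 0.1-bit edge floor applies.

Numerical choices:

- 1-D and 2-D covariance determinants use closed forms, which makes
  MI(x,y) equal to MI(y,x) bit-for-bit; 3-D and larger use a Cholesky
  factorization.
- A diagonal ridge (1e-8·trace(C)/d, escalated once to 1e-6) is applied
  **only when** the plain factorization fails, so well-conditioned
  inputs keep their exact determinants.  If the ridge cannot rescue the
  matrix, a degenerate-input error names the offending variables.
- Numerically collinear pairs (e.g. x passed twice) saturate at the
  normalization ceiling instead of erroring; constant vectors error.

### Normalization

Perfect dependence has infinite MI for continuous variables, so
normalized MI/CMI divide by the value at correlation 1−ε with ε = 1e-6
(max = −½ ln(2ε−ε²) ≈ 6.561 nats) and clamp to [0, 1].  ε is
configurable; any ε ≪ 1 gives the same ordering of edges, and the
normalization only rescales the statistic fed to the significance test.

### Permutation significance

Sample order of x and y is shuffled independently `n_perm` times
(default 100) while any conditioning variable stays fixed.  Each null
statistic and the observed one pass through the Fisher transform
z' = ½[ln(1+r) − ln(1−r)]; the score is Z = (z_obs − mean_null)/sd_null
with a two-sided normal p-value, 2·Φ(−|Z|).  Permutations are seeded;
inside the network pruner the seed is derived from (master seed, sorted
edge ids, conditioner id), so results are independent of iteration
order and of how work might be scheduled.

The statistic fed to the Fisher transform is configurable:

- `stat="correlation"` (default): the signed sample (partial)
  correlation.  Its permutation null is symmetric and close to normal,
  so the normal-tail p-value is well calibrated (measured type-I ≈ 0.05
  at the 0.05 level); on Gaussian data thresholding |r| is equivalent to
  thresholding MI/CMI, which are monotone in |r|.
- `stat="normalized_mi"`: the normalized MI/CMI in [0, 1).  This folded
  statistic has a right-skewed null, and squeezing it through a normal
  tail runs liberal (≈3% type-I at a nominal 1%), which measurably
  inflates spurious edge retention in dense neighborhoods.  It is kept
  as an option because it is the more literal reading of scoring "the
  MI statistic" itself.

The default was chosen because the Fisher transform is a
correlation-domain tool and only the signed statistic makes its null
behave; this is the single most consequential design decision in the
package.

## PC-algorithm pruning

Order-1 conditioning only: common neighbors are tested one at a time,
which matches the intended use (sparse regulatory neighborhoods) and
keeps the cost at O(E·k).  Within a CMI sweep, removals are deferred to
the end of the sweep so the output does not depend on edge iteration
order; a single sweep is the default, with an iterate-to-fixpoint flag.
Defaults: p_cutoff = 0.01, MI floor 0.1 bits (strict: an edge at exactly
the floor is removed), n_perm = 100, seed = 0.

## DRE calling

Windows are ±300 kb around the target TSS (closed interval), promoter
class at |distance| ≤ 2 kb (closed).  Coordinates: BED input is 0-based
half-open and converted to 1-based inclusive; probe position is the
interval midpoint; gene TSS is the interval start on '+' and end on '−';
signed distances are measured 5'→3' along the gene's strand and
classification uses |distance|.  A probe may appear in pairs with
several genes; duplicate (probe, gene) pairs from overlapping windows
keep the smallest p-value.  A zero Pearson correlation is classified
"positive" (logged tie rule).  Differential-expression direction is
consumed from a user table (gene, log2fc, adj_p) filtered at
|log2FC| > 0.58 and adjusted p < 0.01; the bundled two-group Welch t is
plumbing, not a moderated fit.

Precision against chromatin-interaction anchors considers only
negatively correlated pairs; a pair is confirmed when the probe position
falls in one anchor and the TSS ± 2 kb overlaps the mate anchor, either
orientation.  The gene-side ±2 kb promoter proxy is a declared
convention, since an interaction dataset anchors regions, not genes.

## Master regulator analysis

Regulon candidates are genes with permutation-significant MI to the TF.
DPI: in every triangle (TF, g1, g2) whose three edges are all
significant, the weakest edge is removed when it is below
(1 − tolerance)·(second-weakest), tolerance 0.1; removals are collected
over all triangles before being applied, so an edge strictly stronger
than both others in its triangle is never removed.  Members split by the
sign of Spearman correlation with the TF.

Enrichment uses a deterministic rank-sum (Mann–Whitney) test per side
against the ranked Welch-t signature — regulon(+) vs the upregulated
side and regulon(−) vs the downregulated side in run 1, reversed in run
2 — with a Kolmogorov–Smirnov alternative behind a flag.  Side p-values
combine by Fisher's method (−2Σln p against χ² with 4 df), run p-values
are Benjamini–Hochberg adjusted across TFs, and direction is called by
which run wins when the best q passes the threshold (default 0.05).
An empty regulon yields "ns" with a warning rather than an error.

## Enrichment statistics

Odds ratio OR = (a/c)/(b/d) with CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d));
a zero cell is a hard error unless the Haldane +0.5 correction is opted
in, because the formulas are undefined at zero.  The category background
is the union of the four sign/direction subgroups.  Hypergeometric
enrichment reports the upper tail P(X ≥ x) and fold change (x/n)/(K/N).
Motif association uses ±250 bp flanks, closed at the boundary; motif-hit
quality filtering is treated as a property of the input file.

## Circuits and motifs

A TF auto-loop requires a distal DRE of that TF overlapping a
super-enhancer and carrying the TF's own motif within the flank; a cross
edge t1→t2 requires such a DRE of t2 carrying t1's motif.

The triad table is built at import by generating all 64 labeled 3-node
digraphs, keeping the weakly connected ones, and canonicalizing over the
6 node permutations; exactly 13 isomorphism classes result.  Class ids
1–13 order canonical forms by (edge count, canonical 6-bit code):

| class | triad type | class | triad type |
|-------|-----------|-------|-----------|
| 1 | 021D | 8  | 120U |
| 2 | 021C | 9  | 201  |
| 3 | 021U | 10 | 120C |
| 4 | 111U | 11 | 120D |
| 5 | 030T (feed-forward) | 12 | 210 |
| 6 | 111D | 13 | 300 |
| 7 | 030C (cycle) | | |

The census counts every weakly connected node triple once (census
semantics, not per-embedding); self-loops are ignored.  Z-scores compare
against 200 (default) randomized networks; the default null preserves
each node's in- and out-degree exactly via directed double-edge swaps
(10·|E| attempted swaps per replicate), with an Erdős–Rényi same-|V|,|E|
alternative behind a flag.  Where a class's null sd is 0, Z is 0 if the
observed count equals the null mean and ±inf (flagged) otherwise.

## Synthetic scenes and the FDR benchmark

A scene is a latent linear Gaussian system: probe latents m_i ~ N(0,1);
the target gene is effect_size·Σ(±m_causal) + N(0, noise_sd²); observed
methylation is the logistic squash of the latents into (0,1); probes and
any extra genes get seeded random coordinates inside the window.
Confounding is probe-mediated in single-gene scenes (a free probe's
latent is 0.7·m_causal + noise, so it reaches the gene only through the
causal probe) and gene-mediated in multi-gene scenes (a free probe's
latent drives a mediator gene which feeds the target).  Defaults — 300
samples, 30 probes, 3 direct edges, 5 confounders, effect size 0.8 of
the noise scale — give per-edge detection power around 0.9 and are the
conditions under which the error-control benchmark is quoted.

The FDR experiment runs the full calling pipeline per replicate on the
scene (true calls = planted direct edges; false = everything else) and
on a null copy in which the methylation matrix's sample order is
permuted against the expression matrix — destroying every probe–gene
dependence while preserving marginals and probe–probe structure
("chance calls").  FDR = false/(false+true) aggregated over replicates.
At the defaults (20 scenes) the aggregated FDR lands at 0–0.03 at the
p < 0.01 cutoff, i.e. at or below the 0.05 level the pipeline targets.

What the synthetic scenes do **not** emulate: array chemistry (type
I/II probe bias), batch effects, copy-number confounding, non-linear or
threshold regulation, and the heavy-tailed, zero-inflated structure of
real RNA-seq.  Passing the benchmark shows the pruning logic controls
false discoveries under its own modeling assumptions (linear effects,
Gaussian noise); it does not certify error rates on cohort data.

## Known limitations

- Order-1 conditioning cannot separate edges whose confounding requires
  conditioning sets of size ≥ 2.
- The Gaussian MI estimator captures monotone, roughly linear
  dependence; strongly non-linear regulation is invisible to it.
- The degree-preserving swap null can mix slowly on very small or very
  dense graphs; the rigid-graph case (no legal swaps) collapses to
  Z = 0 by construction.
- The CLI is single-process; determinism is guaranteed by keying every
  permutation on (seed, edge), so a parallel driver over genes would
  reproduce identical results, but none is bundled.
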