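# Methods

This note describes what `stagecna` computes, in its own terms, with enough
detail to re-derive every number the package produces.

## Data model

The input is a ternary aberration call matrix **A** (N samples × M probes):
`+1` copy-number gain, `−1` loss, `0` neutral, with a probe map giving each
marker a chromosome and a 1-based inclusive base-pair position. Probes are
kept in genome order (chromosomes in order of first appearance, positions
ascending within a chromosome); all detection operates per chromosome block.
Samples carry a pathological stage label; every stage is analysed
independently. **A** is split into two binary indicator matrices, gains
`AL = (A == +1)` and losses `AD = (A == −1)`, each analysed separately.

Continuous log2-ratio or segmented (SEG) input can be discretised with
`discretize_log2` (strict thresholds; ties and the open interval map to
neutral; non-finite values are an error) and `expand_segments`.

## Marker significance

The null hypothesis at marker *j* is that aberrations land anywhere on the
chromosome with equal probability, while each sample keeps its per-chromosome
aberration load. Formally, the null is a uniformly random permutation of each
sample's calls within each chromosome, independently across samples. Under
that null the count of aberrant samples at a fixed marker of an
`M_c`-marker chromosome is a sum of independent Bernoulli variables with
success probabilities `k_i / M_c` (`k_i` = sample *i*'s load) — a
Poisson-binomial distribution.

Rather than materialising `n_perm` shuffles, `permutation_pvalues` evaluates
the Poisson-binomial tail exactly (iterated convolution of the per-sample
Bernoulli PMFs, O(N²) per chromosome) and reports the *expectation of the
add-one permutation estimator*:

```
p_j = (1 + n_perm · P(null count ≥ observed count)) / (1 + n_perm)
```

This is the Rao–Blackwellised version of the usual add-one Monte-Carlo
estimator: identical in expectation, zero Monte-Carlo variance, and it keeps
the conventional `1/(1 + n_perm)` floor so `n_perm` (default 10,000) still
bounds the smallest reportable p-value. The test suite checks this closed
form against exhaustive enumeration of every joint arrangement of every
binary matrix with ≤ 3 samples and ≤ 4 markers (5,008 matrices).

P-values are converted to q-values with the Benjamini–Hochberg procedure
(via `statsmodels`), genome-wide within one stage and aberration type.
Markers with `q < q_thr` (default **0.10**) are significant.

## Homogeneity

For adjacent markers *j*, *j+1* the per-sample inhomogeneity is

```
H[i, j] = |A[i, j] − A[i, j+1]| / 2
```

i.e. 0 when the ternary state is unchanged, ½ when exactly one side is
neutral, 1 when the states are opposite aberrations. On a binary matrix this
reduces to 0 for no change and ½ for a change. The junction profile
`h_j = mean_i H[i, j]` is therefore half the fraction of samples whose state
changes across the junction, which is the quantity boundary expansion needs:
a junction interior to a common aberrant block has `h ≈ 0`, a junction at the
block edge has `h ≈ frequency/2`. (An alternative convention that scores
two neutral samples as "medium" homogeneity makes every junction of a
partially-penetrant region inhomogeneous and stalls expansion; it is not
used.)

## Region growth and homogeneous peel-off

Per stage and type, up to `max_iterations` (default 10) rounds:

1. If no marker has `q ≤ q_thr`, stop.
2. Take the peak = marker with the smallest q (ties → lowest genome rank).
3. Expand left while the next marker satisfies `q ≤ q_thr` **and** the
   junction crossed satisfies `h ≤ h_thr` (default **0.12**); expand right
   symmetrically. Expansion never crosses a chromosome boundary.
4. Record the region `[l, r]` (probe ranks and bp bounds, peak q, carrier
   frequency, iteration).
5. Peel off: zero the calls of the samples aberrant *at the peak* across
   `[l, r]` only, and recompute significance.

Peeling only the peak's carriers (homogeneous peel-off) lets overlapping
secondary events with a different carrier population reach significance in
later rounds.

`find_shared_runs` is a separate exploratory view: maximal biclusters of a
contiguous marker interval × the full set of samples sharing one identical
non-zero state, with minimum span and sample-count thresholds.

## Annotation, pathways, network

* **Genes**: a gene is assigned to a region iff fully contained,
  `region.start_bp ≤ gene.start` and `gene.end ≤ region.end_bp` (1-based
  inclusive in memory; BED files use the standard 0-based half-open
  convention on disk). Amplified and deleted gene sets are kept per stage.
* **Pathways**: each stage's pooled aberrant genes (amplified ∪ deleted) are
  intersected with a GMT pathway database. Pathways are kept if their full
  size is strictly greater than `min_pathway_size` (default 5) and they are
  hit in at least `min_stages` (default 2) distinct stages.
* **Network**: for every adjacent stage pair (s, s+1) in the given stage
  order, every pair of *distinct* surviving pathways with intersecting gene
  sets gets an edge weighted `W = k² / (p·q)`, where k is the shared gene
  count and p, q the two gene-set sizes; `W ∈ (0, 1]`, and `W = 1` iff the
  sets coincide. The default gene basis is the stage-specific *hit* sets
  (what was actually aberrant at each stage); `gene_basis="full"` uses the
  database definitions instead. The container is a `networkx.MultiGraph`
  keyed by the stage pair, since one pathway pair can be linked across
  several stage transitions with different weights.

## Simulator

`simulate_stage_calls` emulates a staged cohort: i.i.d. background gains and
losses at `background_rate` per cell (collisions resolved by a seeded coin
flip), plus planted regions, each with a stage, chromosome span, type,
carrier frequency, and a `carrier_overlap` fraction controlling how many
carriers span the full region versus a random sub-span. Stage streams are
split from one master `SeedSequence`, so adding a stage never perturbs
another stage's data. It does **not** model probe-level intensity noise,
segmentation error, purity/ploidy, or correlated co-occurrence of events —
it generates calls, not raw copy-number signal.

`simulate_gene_annotation` places genes uniformly with uniform lengths.
`simulate_pathway_db` draws each pathway's shared part from a common pool of
`max(size_range)` genes and fills up with private genes, giving the diffuse,
hypergeometric pairwise overlaps of real pathway collections while staying
exact at the extremes (overlap 0 → pairwise disjoint; overlap 1 with equal
sizes → identical sets).

## Problem sizes and numerics

The bundled study (`scripts/acceptance.py`) uses four stages with 9/46/145/19
samples, 2,000 probes over four 500-probe chromosomes (1 kb spacing), nine
planted regions of 40–50 probes at frequencies 0.3–0.6, 1,500 genes of
1–25 kb, and 40 pathways of 10–80 genes at overlap fraction 0.5. One full
pipeline run takes about a second; the Poisson-binomial convolution is the
only super-linear step (O(N²) per chromosome) and is negligible at cohort
sizes of a few hundred samples. All p/q arithmetic is float64; the tail is
clipped to [0, 1] to absorb convolution round-off. Every random draw in the
package flows from explicit integer seeds through `numpy` `SeedSequence`
spawning, and pipeline outputs contain no timestamps, so reruns are
byte-identical.

## Limitations

* Marker significance treats samples as exchangeable and markers within a
  chromosome as interchangeable under the null; real probe spacing and local
  GC/wave artefacts are not modelled.
* The FDR threshold of 0.10 admits occasional background regions (by design);
  the background-only guard in the test suite bounds how often.
* Stage assignments are taken as ground truth; no uncertainty in staging is
  propagated.
* The evolution network connects pathways by gene sharing only; it does not
  model directionality or causality between stages.
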