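# Methods

## Models

Three static discrete Bayesian networks over binary nodes describe an
18-gene Wnt-pathway panel (including two separate DKK3 probes, `DKK3-1`
and `DKK3-2`) in colorectal tissue. State index 1 is always the low/off
pole (normal, inactive, low concentration, non-methylated), index 2 the
high/on pole.

**t1** (34 nodes) encodes prior biological knowledge plus epigenetic
information. Gene parent sets follow the published tables:

* `{Sample}`: DKK2, DKK3-1, DKK3-2, SFRP3, LEF1
* `{Sample, TRCMPLX}`: MYC, CCND1, CD44, DKK4
* `{Sample, Me<gene>}`: DACT1, DACT2, SFRP2, SFRP4, SFRP5
* `{Sample, Me<gene>, TRCMPLX}`: DKK1, SFRP1, WIF1
* `{H3K27me3, H3K4me3, Sample}`: DACT3

plus the transcription machinery `DVL2 ← DACT3`,
`BETACAT ← DACT1, DVL2`, `TRCMPLX ← TCF4, LEF1, BETACAT`. The `Sample`
node (tissue status) is a root segregated from `TRCMPLX`; genes without a
confirmed complex relation connect to the rest of the model only through
it, which is exactly the d-connectivity structure probed by
`enumerate_simple_paths` / `is_d_separated`.

**t2** (23 nodes) removes all methylation and histone nodes and their
arcs. **p1** (21 nodes) is a naive-Bayes design: all 18 genes read
`TRCMPLX` only, which reads `BETACAT` and `TCF4`; there is no `Sample`
node, activation of the complex standing in for tumor status.

One structural ambiguity exists in the source: DKK4's printed conditional
table has four columns (parents `{Sample, TRCMPLX}`) while the
surrounding text groups DKK4 with the methylation-regulated genes. The
printed dimensionality is taken as authoritative; `TopologyOptions
(include_me_dkk4=True)` adds the `MeDKK4 → DKK4` arc, replicating the
printed table across both methylation states so the option is
value-neutral. `MeDKK4` remains in the t1 inventory as an isolated root
either way. The path count between SFRP3 and TRCMPLX is invariant to the
flag because methylation nodes are path dead ends.

## Fixed parameters

Non-gene nodes carry fixed tables (packaged in
`wntbn/data/reference_parameters.json`): the 50/50 tissue prior, TCF4
(0.1/0.9), the DVL2–DACT3 inverse link (0.01/0.99 pattern), the
β-catenin table (high only when DACT1 is expressed *and* DVL2 is high),
the complex AND-gate (active at 0.99 only when all three constituents are
high), seven methylation priors and two histone-mark priors derived from
normalized wet-lab measurements. No prior is published for `MeDKK1`/
`MeDKK4`; both default to 0.5/0.5 and are configuration-overridable.
For p1 the source prints no BETACAT root prior nor a 2-parent complex
table; the package defaults to 0.5/0.5 and an AND-gate mirroring the t1
pattern. A few printed gene-table columns sum to 0.99/1.01 (two-decimal
rounding); they are stored verbatim and column-normalized on load.

## Gene-CPT estimation

Per training fold and gene: the threshold is the sample median of the
gene's training values; a value strictly below it is state 1, at or above
it state 2. The same rule discretizes test evidence. (The source uses
overlapping `≤/≥` comparisons in training and strict `<` at test time; a
single strict rule keeps the counts a partition and training consistent
with testing.) Counts per fold: `a`/`c` active/inactive in normal, `b`/`d`
in tumor; `A..D` are rule-specific denominators.

With `p = 1 − ETGN` (ETGN = assumed effect of the complex on its targets,
default 0.9, sweep {0.5..0.9}; `p` multiplies the complex-off block and
`1 − p` the complex-on block):

* **Sample only** — `Pr(on|N) = a/(a+c)`, `Pr(on|T) = b/(b+d)`.
* **Sample, TRCMPLX** — `Pr(on|N,off) = a·p/A` with `A = a+c`,
  `Pr(on|T,off) = b·p/B` with `B = b+d`, `Pr(off|N,on) = (A−a)(1−p)/A`,
  `Pr(off|T,on) = (B−b)(1−p)/B`.
* **Sample, Me, TRCMPLX** — cross-table rule with the published mixed
  denominators `A = (a+c)+b`, `B = (b+d)+a`, `C = (a+c)+d`,
  `D = (b+d)+c`: `Pr(on|N,UM,off) = a·p/A`, `Pr(on|T,UM,off) = b·p/B`,
  `Pr(off|N,M,off) = c·p/C`, `Pr(off|T,M,off) = d·p/D`; complex-on block
  analogous with `1 − p`. The denominators deliberately mix classes; they
  are implemented exactly as derived, not "corrected".
* **Sample, Me** — the cross-table rule with the complex factor removed
  (this case is never derived explicitly in the source; the analogy is
  the package's choice).
* **DACT3** — `Pr(on | K27 low, K4 high, class) = actives/class size`;
  every other histone configuration flips to the complement. Parent order
  `(H3K27me3, H3K4me3, Sample)` follows the printed table layout.
* **TRCMPLX only (p1)** — class labels proxy the complex state
  (normal ↔ off): `Pr(on|off) = a/(a+c)`, `Pr(on|on) = b/(b+d)`; no ETGN
  weighting.

Every column then receives +1 pseudo-count smoothing and renormalization,
eliminating deterministic 0/1 entries. As published, the constant is
added to the *fraction-valued* table; `smoothing_on="counts"` switches to
the count scale (classic Laplace smoothing) for sensitivity analysis.
The two differ materially: fraction smoothing shrinks every entry toward
½ by a fixed factor of 3 regardless of sample size, so estimates do not
converge to generating frequencies as n grows — parameter-recovery
checks therefore run in counts mode, where the pseudo-count washes out.
A column whose denominator is zero (a class absent from the fold) is
left empty and becomes uniform after smoothing.

Column convention throughout: the first-listed parent varies fastest; a
parent configuration `(s_1..s_k)` maps to column `Σ (s_i−1)·2^(i−1)`.

## Inference

Exact marginals via variable elimination with a greedy min-fill ordering
(deterministic name tie-break); the networks are small and sparse, so any
exact method suffices and the contract is exactness. A fresh elimination
state is constructed per query — reusing an engine already conditioned on
other evidence silently corrupts posteriors, so an instrumentation
counter (`engine_build_count`) lets experiment code assert freshness.
Zero-probability evidence raises `ImpossibleEvidenceError` rather than
returning NaN. The independent oracle `brute_force_marginal` materializes
the full joint by array broadcasting (guarded at ≤ 24 nodes ≈ 134 MB) and
sums it; the elimination path is required to agree within 1e-9 on the
full t2/p1 networks and on random sub-networks.

## Holdout design

Exhaustive leave-pair-out: each of the `n_normal × n_tumor` ordered pairs
(normal outer loop, tumor inner) forms the test set; the training fold is
everything else, so a 24+24 cohort yields 576 iterations with 46-sample
folds. Both test samples of a pair are discretized against the same
fold-derived thresholds. Per test sample (not per pair — scoring consumes
per-sample scores with ±1 labels) the posteriors
`Pr(TRCMPLX=active | evidence)` and, for t1/t2,
`Pr(Sample=tumor | evidence)` are recorded. In `ge` mode the evidence is
the discretized state of all 18 genes; in `me` mode it is one of the
2^9 = 512 binary methylation configurations (optionally a seeded
subsample to bound runtime; default exhaustive). Reruns with the same
data and configuration are bit-identical.

## Evaluation

ROC by threshold sweep over the distinct scores with trapezoidal AUC
(ties grouped; endpoints anchored at (0,0) and (1,1)). The KS comparison
uses the asymptotic two-sample statistic with the standard effective-n
correction; the source reports only the rejection flag, so α defaults to
0.05 as the package's choice. The per-gene summary groups test samples by
a gene's evidence state within each true class, averages the complex
posterior, and reports the majority-state mean as the inferred belief;
majority ties break toward repressed, and an empty group is flagged
`no_evidence` instead of propagating NaN.

## Synthetic cohorts

The generator ancestrally samples every latent node from the packaged t1
parameter set in topological order from a single seeded generator, with
`Sample` clamped (conditioning by intervention) so class counts are
exact, then emits expression as a two-component Gaussian
(`mu_low = 0`, `mu_high = 1`, `sigma = 0.25` by default; the source never
models continuous expression, so any state-separable emitter preserves
what the analysis consumes — the median split). Defaults emulate the
study cohort: 24+24 balanced samples, 18 gene rows.

What it does *not* emulate: real expression magnitudes and heavy tails,
probe-level noise correlation, and any dependence between genes beyond
the network structure. Passing tests on synthetic cohorts therefore
demonstrate correctness of the pipeline's mechanics and its qualitative
behavior (Sample predictions dominating TRCMPLX predictions, KS
separation of the two), not the published cohort-specific AUC values,
which would require the undeposited matrix.

A note on the median split: with `sigma = 0` a gene whose pooled active
fraction is far from ½ has its median collapse onto one component and the
split becomes uninformative; the printed single-parent tables are
class-symmetric (pooled fraction ≈ ½), which is what makes the design
workable. Recovery and closure tests use `sigma = 0.02`, n = 2000/class.

## Problem sizes and numerical choices

Test and acceptance runs use: the full 576-iteration holdout on a 24+24
cohort (seconds per variant), 2000/class cohorts for parameter recovery,
8-node random DAGs with exhaustive conditioning sets for the
d-separation oracle sweep, and ≤ 15-node random networks for inference
oracle equivalence. Probability-equality assertions use 1e-9; CPT column
sums are enforced to 1e-12 after normalization. ETGN applies only to
genes with the complex as a parent.

## Known limitations

* Static snapshot only; no time-course dynamics.
* No structure learning or model scoring — the three DAGs are fixed.
* Binary nodes throughout; continuous evidence is out of scope.
* The `{Sample, Me}` estimation rule and the p1 fixed tables are
  analogy-based package choices where the source is silent.
* The fraction-scale smoothing (as published) is a fixed shrinkage toward
  ½, not a consistent estimator; use `smoothing_on="counts"` when
  asymptotic fidelity matters.
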