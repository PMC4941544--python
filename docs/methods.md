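# Methods

## Model and pipeline

`orthopath` treats pathway analysis of unmatched multi-study, multi-omic
expression data as two nested integration problems.

**Per study.** Each study is a feature-by-sample matrix of log2
intensities with a two-group design. For every feature the standardized
mean difference (Cohen's d, disease minus control, so positive means
up-regulated in disease), its sampling variance V_d, and the bias-corrected
Hedges' g = J(n)·d are computed; J is evaluated through log-gamma so it is
stable for any realistic group size. The standard error of g is taken as
J(n)·√V_d — the common first-order choice rather than the exact variance of
g; the difference is negligible beyond a handful of samples. Differential
expression is tested two-sided by one of: pooled-variance t, Welch t, or
the default moderated t.

**Moderated t.** Per-feature variances are shrunk toward a common prior
s₀² with prior degrees of freedom d₀, estimated by moment-matching the log
sample variances: with e_g = log s_g² − ψ(d_g/2) + log(d_g/2),
Var(e) = ψ′(d_g/2) + ψ′(d₀/2) and E(e) = log s₀² − ψ(d₀/2) + log(d₀/2)
(ψ, ψ′ di/trigamma; the trigamma equation is inverted by Newton iteration).
If the observed spread of log variances does not exceed the pure chi-square
expectation, the prior is degenerate (d₀ = ∞) and all features share s₀².
The test statistic uses the posterior variance
(d₀s₀² + d_g s_g²)/(d₀ + d_g) on d₀ + d_g degrees of freedom. This is the
standard empirical-Bayes construction; numerical equality with any
particular external implementation is not a goal.

**Across studies (horizontal).** Feature-wise, the per-study g and
variances enter the random-effects model y_i = μ + u_i + e_i,
u_i ~ N(0, τ²), e_i ~ N(0, v_i). τ² is estimated by REML: the restricted
log-likelihood

    −½[ Σ log(v_i+τ²) + log Σ w_i + Σ w_i (y_i − μ̂)² ],  w_i = 1/(v_i+τ²)

is maximized over τ² ∈ [0, 10·var(y) + max v] by bounded scalar
(golden-section/parabolic) search with tolerance 1e-8; μ̂ is the
inverse-variance weighted mean at τ̂², se(μ̂) = (Σw_i)^{−1/2}. The boundary
τ² = 0 is checked explicitly. Features measured in only a subset of studies
are combined over that subset; no imputation.

Per-study p-values (two-sided) are combined by add-CLT: the sum of m
p-values has the Irwin–Hall distribution, evaluated for m < 20 by the
alternating-sum formula with log-domain binomial terms and compensated
summation (absolute error < 1e-5 up to m = 19), and for m ≥ 20 by the
central-limit approximation on the mean, N(1/2, 1/(12m)). The switch point
20 is configurable. Degenerate inputs: p = 0 is clamped to 1e-300 with a
warning (Fisher/Stouffer transforms diverge at 0).

**DE selection.** BH-FDR is applied separately within the mRNA and miRNA
panels (they come from disjoint study sets). DE features are those with
FDR < 0.05, keeping the largest |μ̂| up to 10% of the measured features of
that type ("up to": fewer when fewer are significant). Ties on |μ̂| break
by smaller combined p, then feature id, so selection is deterministic.

**Pathways (vertical).** Gene pathways are augmented by adding every miRNA
with at least one on-pathway target, connected to those targets with
repression edges (type overridable per interaction record). Augmentation
never touches existing nodes or edges and is idempotent. Edge weights:
+1 activation-like, −1 repression-like, 0 binding; any other relation must
be mapped explicitly in the weight table (fail-fast rather than a silent
zero).

Each augmented pathway is scored by:

- P_NDE: hypergeometric tail P(X ≥ observed DE on pathway) with the
  universe equal to the union of all measured mRNA and miRNA features.
  Unmeasured pathway nodes do not count as measured and get ΔE = 0.
- P_PERT: the perturbation factors solve (I − M)·PF = ΔE with
  M_gu = β_ug/N_ds(u) (N_ds = number of distinct successors); ΔE is the
  REML μ̂ for DE nodes and 0 otherwise. Acc = PF − ΔE and the statistic is
  the signed sum ΣAcc(g). Because that sum is linear in ΔE, the
  implementation precomputes s = 1ᵀ(I−M)⁻¹ − 1ᵀ once per pathway, making
  each permutation a dot product. The null reassigns the observed nonzero
  ΔE multiset uniformly over the pathway's measured nodes (genes and
  miRNAs alike; a genome-wide resampling variant is available); the
  p-value is two-sided around the null median with a +1 pseudo-count, so
  it is strictly positive and exactly reproducible from the seed. If
  (I − M) is singular (a feedback loop with net gain 1), M is damped once
  by 0.99; a pathway still singular after damping is excluded from ranking
  and reported separately.
- Combination: c = P_NDE·P_PERT, combined p = c − c·ln c (the survival
  function of a product of two independent uniforms).

Pathway p-values are BH-adjusted over the analyzed (non-singular)
pathways; ranking is by combined p ascending with ties broken by larger
|ΣAcc|, then pathway id. One master seed spawns per-pathway permutation
streams by hashing the pathway id, so adding or removing a pathway leaves
the others' P_PERT unchanged.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `de_fdr` | 0.05 | FDR cutoff before top-|SMD| selection |
| `de_top_frac` | 0.10 | cap on DE features per data type, fraction of measured |
| `combiner` | add_clt | per-feature p-value combination |
| `test_method` | moderated_t | per-study DE test |
| `n_perm` | 2000 | permutations per pathway (p_pert resolution 1/2001) |
| log2 threshold | 50 | matrix max above this triggers log2(x+1) rescaling |

## Synthetic data

The generator emulates exactly the structure the model assumes: per-study
true effects δ_s ~ N(μ_effect, τ²) for planted features, zero otherwise;
control samples N(baseline, σ²), disease samples N(baseline + δ_s·σ, σ²),
so the population SMD in study s equals δ_s by construction (this makes
parameter-recovery assertions exact in expectation). Baselines are drawn
once per feature from N(8, 2²) to mimic log2 microarray intensities.
Defaults: 5 mRNA and 3 miRNA studies, 10 samples per group, 200 genes and
40 miRNAs, ten disjoint 10-gene pathways (chain backbone plus random
forward edges, hence acyclic), 60% of the planted pathway's genes DE at
μ_effect = 1.0 with τ² = 0.05, unit noise SD; the planted pathway's miRNAs
carry the opposite-signed effect and repress planted genes. Study sizes of
10 per group are at the low end of public expression series, a deliberately
conservative power regime.

What the generator does **not** emulate: probe-level effects, batch
structure beyond the between-study random effect, platform-specific
intensity distributions, count-based RNA-seq noise, or correlated
features. Passing tests therefore demonstrate correctness of the
statistics and the pipeline logic under the model's own assumptions, not
robustness to real-data artifacts.

## Design choices where the design was open

- Effect-sign convention: d = (disease − control)/S_pooled.
- Per-study p-values entering the combination are two-sided.
- ΔE is the REML μ̂ as-is; no additional transform of the SMD is applied
  before propagation.
- The P_NDE universe is the union of measured features across studies;
  per-study availability is handled at the meta step.
- miRNA identifiers are lowercased before any comparison (nomenclature is
  case-inconsistent across sources); gene symbols are case-sensitive.
- Multi-probe collapsing is preprocessing outside the tool: inputs are one
  row per feature.
- BH is applied within each data type for features, and across analyzed
  pathways for the final ranking.

## Known limitations

- With small pathways in which most measured nodes are DE with
  similar-sized effects, permuting ΔE over the pathway barely changes the
  accumulation, so P_PERT is near-uniform and dilutes strong P_NDE
  evidence. Under the default simulation conditions the planted pathway is
  ranked first essentially always, while its FDR clears 0.05 in roughly
  nine out of ten collections.
- REML standard errors carry no small-m correction (no Hartung–Knapp), so
  confidence coverage can dip slightly below nominal for very few studies.
- The moderated-t prior assumes a common variance distribution across
  features (no intensity trend).
- Pathways are scored independently; overlapping pathways share evidence.
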