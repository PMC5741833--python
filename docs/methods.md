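# Methods

`refstab` implements the standard workflow for choosing qRT-PCR reference
(housekeeping) genes: screen candidates for expression evenness on array
data, measure the panel by qPCR, score stability with four established
algorithms, aggregate the four rankings into a comprehensive score, and
verify that the chosen references do not distort ΔΔCt fold changes. This
note records the models, the tunable parameters, and the numerical and
design choices, in enough detail to reproduce every number the package
computes.

## Stability algorithms

All four methods consume a complete genes × units matrix of Ct values,
where a *unit* is one biological replicate of one sample and technical
replicates have already been collapsed (mean by default). Where a method
works on expression rather than cycles, Ct is first transformed to relative
quantities q = E^(minCt − Ct) with E the per-gene amplification factor per
cycle (default 2.0, i.e. 100% efficiency); each gene's most abundant unit
then has q = 1. All logarithms are base 2.

**geNorm.** The pairwise variation of genes j, k is the SD across units of
log2(q_j/q_k); a gene's M value is the mean of its pairwise variations. If
two genes are regulated proportionally their ratio is constant and both
pairwise terms are zero — geNorm's ideal. The ranking is stepwise: record
M, drop the gene with the largest M, recompute, until two genes remain.
The reported score of an excluded gene is its M at the step of exclusion;
the final two genes are scored with their mutual pair SD and share rank
1.5 (they are indistinguishable to the method). `stepwise=False` returns
the plain full-panel M instead, which at E = 2 coincides exactly with the
comparative-ΔCt score (see invariants below). The companion statistic
V(n/n+1) — the SD of the log ratio of normalization factors built from the
n and n+1 best genes — is exposed for choosing how many references to use.

**Comparative ΔCt.** The score of gene j is the mean over partners k of
the SD across units of (Ct_j − Ct_k). No transformation is needed;
per-unit loading offsets cancel in the difference.

**NormFinder.** Works on z = y − ȳ_unit, the sample-centered log2
quantities, which removes the common loading component. Ungrouped (the
default when no condition labels exist): score = SD of z across units.
Grouped: with intragroup variances s²_gj, group-mean deviations d_gj from
the gene's overall mean, and a between-group variance estimate
γ̂² = max(0, Var_j(d_gj) − mean_j s²_gj/n_j), the group deviations are
shrunk by γ̂²/(γ̂² + s²_gj/n_j) and the score is the mean over groups of
|d̃_gj| + sqrt(γ̂² (s²_gj/n_j)/(γ̂² + s²_gj/n_j)). A gene that shifts
systematically between conditions is penalized even when its within-group
variance is small. Var_j over groups uses the J−1 denominator; published
descriptions of the estimator differ in small-sample correction constants,
so this implementation is validated against an independent brute-force
re-derivation rather than against any specific historical script.

**BestKeeper.** A descriptive method on raw Ct: the dispersion is the mean
absolute deviation about the gene's arithmetic mean (option: sample SD),
genes above 1 cycle are flagged inconsistent, and each gene's Pearson
correlation with the BestKeeper index (per-unit geometric mean Ct) is
reported. Because it never forms ratios, BestKeeper is *not* invariant to
per-unit loading shifts — a documented contrast with the other three.

**Comprehensive score.** A gene ranked r_1…r_4 by the four methods gets
the geometric mean (r_1·…·r_4)^(1/4), re-ranked ascending with average
ranks for ties. Scores are therefore in [1, G].

**Iterative (circular) assessment.** geNorm, NormFinder and ΔCt scores
depend on the competitor panel, so the comprehensive ranking is repeated,
excluding the worst gene each cycle, until two genes win: a G-gene panel
takes exactly G − 2 cycles. Per cycle, geNorm runs its own internal
stepwise procedure on the surviving set (nested exclusion). Ties for the
worst comprehensive score exclude the lexicographically larger gene id, so
reruns are bit-identical. ΔCt scores are recomputed on the shrunken panel
by default; a `cache` mode freezes the full-panel scores instead, since
removing one gene perturbs the remaining pair-averages only slightly (the
trace makes the size of that perturbation visible rather than assuming it
away).

### Invariants the tests enforce

- Adding an arbitrary constant per unit to all genes leaves geNorm,
  NormFinder and ΔCt scores unchanged (≤ 1e-10 drift) and changes
  BestKeeper dispersion.
- At E = 2, geNorm's pairwise variation V_jk equals the ΔCt pair SD
  exactly: log2(q_j/q_k) = (Ct_k − Ct_j) + const. Consequently the
  full-panel M and the ΔCt score are the same statistic, and their
  reciprocal stability scores correlate at exactly r = 1.
- Every statistic (including the stepwise geNorm trace and tie handling)
  agrees with independent naive double-loop implementations to 1e-12 on
  hundreds of random matrices.

## Preselection screen

Per gene (sum of its probes' intensities) and per probe: CV (sample SD
over arrays divided by the mean; n−1 denominator — the convention is not
universal, so it is stated here), mean intensity, and MFC = max/min.
Cutoffs are strict inequalities: CV < 0.11, mean > 1000, MFC < 1.4. A
gene passes probe level if *any* of its probes passes (default; the
permissive rule matches screens that report more probe-level than
gene-level candidates), or *all* probes under the stricter option. The
report carries the gene-level, probe-level and intersection sets.

## Quantification

The standard curve regresses Ct on log10 relative input over a dilution
series (relative input = factor^(−step)); efficiency = 10^(−1/slope) − 1,
so a slope of −3.3219 cycles per 10-fold dilution is 100%. ΔΔCt fold
change: ΔCt = Ct_target − mean Ct_references per unit, ΔΔCt = ΔCt_treated
− mean(ΔCt_control), FC = 2^(−ΔΔCt), summarized as the point estimate
2^(−mean ΔΔCt) with the SEM of per-replicate fold changes. Multiple
references are combined by the arithmetic mean of their Ct — identical to
the geometric mean of their quantities, the geNorm normalization-factor
convention. An efficiency-corrected (Pfaffl-style) ratio is available when
per-gene efficiencies are supplied; at E = 2 everywhere it reduces to the
plain ΔΔCt result. The applicability panel evaluates one contrast under
every candidate reference, exposing how an unstable reference inflates or
deflates the apparent fold change of each target.

## Concordance

Method agreement is the Pearson correlation of per-gene *stability*
scores, defined as reciprocals of the instability scores. A zero
instability (possible for perfect synthetic genes) is capped at 1/ε with
ε = 1e-6 rather than dropped, so such genes still enter the correlation.
Array-based variants: ArrayG = 1/CV of gene-level intensities, ArrayPCV =
1/CV of the gene's minimum-CV probe, ArrayPInt = 1/CV of its
maximum-mean-intensity probe. Pairs sharing fewer than 3 genes, or with a
zero-variance member, are reported as undefined.

## Synthetic data: what it emulates, and what it does not

The Ct generator draws

    ct(g, u, t) = baseline_g + condition_effect_g(cond(u)) + s_u + e_gu + τ_gut

with s_u ~ N(0, σ_sample) shared by all genes in a unit, e_gu ~ N(0,
σ_gene,g), and τ ~ N(0, σ_tech) per technical replicate — additive
Gaussian noise on the Ct scale, the standard qPCR error model. The shared
s_u term is exactly the structure reference-gene normalization assumes,
which is what makes the loading-invariance tests exact. Ground truth per
gene is the designed total instability sqrt(σ_gene² + spread of condition
effects).

Defaults (chosen once, as study conditions, and not tuned): panels of 23
genes across 9 samples with 3 biological × 3 technical replicates;
baselines spread over Ct 17–31; σ_sample = 0.3 cycles, representing the
loading/RT variability of a carefully pipetted replicate series (larger
values are realistic for heterogeneous sample sets but are a property of
the experiment, not the benchmark); σ_tech = 0.1 cycles, typical
within-plate pipetting error. The recovery benchmark gives one gene
σ_gene = 0.05 and spreads the other 22 over 0.4–1.2 cycles.

Randomness uses per-gene substreams keyed by a CRC of the gene id, so
adding a gene to a design does not perturb the other genes' draws; a
single seed makes every dataset bit-reproducible.

The intensity generator constructs each gene's array profile so that the
*realized* gene-level mean, CV and MFC equal the designed targets: the
profile is 1 + (MFC−1)·u with the minimum of u pinned at 0 and the
maximum at 1 (MFC exact by construction), interior points scaled about
their mean by a factor found with Brent's method so the CV lands on
target (CV is continuous and increasing in that factor), then the whole
row scaled to the target mean. Feasibility bound: no positive profile can
exceed CV ≈ (MFC−1)/(MFC+1)·sqrt(n/(n−1)); incompatible target pairs are
rejected with the gene named. Probes split the gene profile
proportionally (probes inherit the gene's evenness), with per-array
Dirichlet shares (individually noisy probes summing to an even gene), or
as fully divergent per-probe profiles. Ground-truth pass/fail labels are
computed by the generator from its own realized matrix with inline
formulas — an independent code path from the preselection module, which
is what makes the exact-agreement test meaningful. Boundary genes are
placed 1e-9 (relative) outside or inside each cutoff: indistinguishable
from "exactly at the cutoff" at any practical precision, but wide enough
that float summation-order differences (~1e-13) between code paths cannot
flip a strict comparison. Exact equality at a cutoff (e.g. MFC of
precisely 1.4) is exercised separately on hand-constructed matrices where
both code paths see identical numbers.

Not emulated: amplification curves and threshold calling, probe
hybridization physics, array spatial artifacts, batch effects between
array sources, and non-Gaussian Ct error (dropouts near the detection
limit are representable only as missing values). Passing the simulation
benchmarks therefore demonstrates correctness of the algorithms and
sensible behaviour under the assumed error structure, not performance on
pathological real-world data.

## Numerical conventions and degenerate inputs

- Sample SDs and variances use the n−1 denominator throughout; BestKeeper's
  dispersion is the mean absolute deviation (n denominator), per its
  definition.
- Rank ties average everywhere; argmax ties (worst gene) resolve to the
  lexicographically larger id, argmax/argmin probe selection to the first
  in sorted order — all runs are deterministic.
- Ct validity is (0, 45] cycles; "Undetermined"/"NA"/empty parse as
  missing; any other non-numeric Ct is a hard error. Genes with missing
  collapsed cells are dropped (with a report) before stability analysis,
  since all four methods require complete matrices.
- A fully proportional (zero-variance-ratio) panel yields all-zero geNorm
  and ΔCt scores; exclusion order then falls back to the lexicographic
  tie-break. Zero-dispersion genes get an undefined BestKeeper index
  correlation but a valid (best) rank.
- Efficiencies must lie in (1, 2.2]; standard curves with non-negative
  slope are rejected as invalid.

## Problem sizes

The test suite and the acceptance script use 200 random 3–5 gene × 3–6
unit matrices for brute-force equivalence, 100 matrices for the
geNorm/ΔCt identity, 100 seeds of the 23-gene recovery design (ranking and
full iterative traces), and one 200-gene × 48-array screen — sizes at
which every check, including the naive O(G²·U) double loops, completes in
well under a minute on a single core while matching the scale of a real
candidate-validation study.

## Known limitations

- The grouped NormFinder estimator is one member of a family differing in
  small-sample corrections; scores from other implementations may differ
  in the third decimal while agreeing in ranking.
- The stepwise geNorm score (M at exclusion) is not the full-panel M; both
  are available, and users comparing against other tools should check
  which convention that tool reports.
- The iterative procedure's behaviour on panels with many exact ties is
  convention-dependent (lexicographic here).
- BestKeeper's correlation-with-index output is descriptive only; ranking
  uses dispersion, as in the original method.
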