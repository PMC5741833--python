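# refstab

Reference-gene (housekeeping-gene) selection for qRT-PCR, as a tested
Python library: evenness preselection of candidates from expression
microarrays, the four standard stability algorithms — geNorm, NormFinder,
comparative ΔCt and BestKeeper — a comprehensive geometric-mean-of-ranks
aggregation with iterative exclusion, ΔΔCt fold-change applicability
checks, and between-method concordance. A synthetic-data module generates
Ct tables, intensity matrices and dilution series with known ground truth,
so every ranking the pipeline produces can be validated against a designed
answer.

**Who it is for.** Anyone normalizing qPCR data who needs to justify the
choice of reference genes: the expression of a target gene is quantified
relative to references assumed stable, so an unstable reference silently
rewrites every fold change downstream.

## The statistics in brief

With Ct the quantification cycle (lower = more transcript) and relative
quantity q = E^(minCt − Ct) at amplification factor E (2.0 at 100%
efficiency):

- **geNorm** — M_j = mean over partners k of SD_u[log2(q_ju/q_ku)];
  stepwise exclusion of the largest M until two genes remain, plus the
  V(n/n+1) statistic for choosing the number of references.
- **NormFinder** — model-based score on sample-centered log quantities;
  with groups, combines intragroup variance with shrunken intergroup
  deviation.
- **Comparative ΔCt** — mean over partners of SD_u[Ct_j − Ct_k].
- **BestKeeper** — mean absolute deviation of raw Ct about its mean, plus
  correlation with the per-unit geometric-mean index.
- **Comprehensive score** — geometric mean of the four ranks,
  (r₁·r₂·r₃·r₄)^¼; applied iteratively, excluding the worst gene each
  cycle until the final two win.
- **Preselection** — gene- and probe-level screen with strict cutoffs
  CV < 0.11, mean intensity > 1000, MFC < 1.4.
- **ΔΔCt** — fold change 2^(−ΔΔCt) with ΔΔCt = ΔCt_treated − ΔCt_control,
  ΔCt = Ct_target − mean Ct_references.

All four methods report *instability* scores: the smaller, the better.
Details, conventions and edge cases are in [docs/methods.md](docs/methods.md).

## Worked example

Rank a simulated 23-gene panel (9 cell lines × 3 biological × 3 technical
replicates) in which one gene was designed ultra-stable (σ = 0.05 cycles):

```python
import refstab as rs

dataset, truth = rs.simulate_ct_dataset(rs.recovery_ct_design(seed=1))
cm = rs.collapse_technical_replicates(dataset)      # 23 genes x 27 units
results = rs.run_all_methods(cm)
for name, res in results.items():
    top = res.to_frame().iloc[0]
    print(f"{name:<12} {top['gene']:<8} {top['score']:.4f}")
```

prints

```
genorm       REF01    0.4262
normfinder   REF12    0.2172
delta_ct     REF12    0.7580
bestkeeper   REF12    0.2510
reffinder    REF12    1.1067
```

`REF12` is the designed stable gene; three methods rank it first outright,
geNorm puts it in its tied winning pair (here `REF01`/`REF12` share rank
1.5, and `REF01` is listed first alphabetically), and the comprehensive
(reffinder) score of 1.11 is the geometric mean of its four ranks — nearly
the perfect 1.0. The iterative assessment then confirms the choice:

```python
trace = rs.iterative_exclusion(cm)
print(trace.final_pair)          # ['REF01', 'REF12'] after 21 cycles
```

The `examples/` directory has one short script per capability:
preselection (`01`), ranking (`02`), iterative assessment (`03`),
efficiency + ΔΔCt applicability (`04`) and concordance (`05`). A thin CLI
(`refstab simulate|preselect|stability|iterate|quantify|correlate|efficiency`)
wraps the same functions for shell use.

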