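# macnet

Analysis toolkit for serum-induced macrophage reprogramming after acute
myocardial infarction (AMI), and for network-guided drug repurposing against
the adverse-remodeling gene program.

Circulating factors in post-infarct serum reprogram macrophages; the
transcriptomic footprint of that reprogramming correlates with clinical
outcome (infarct size, ejection fraction, end-diastolic volume), and the gene
programs specific to large-infarct patients suggest drug targets.  `macnet`
implements the full computational chain a systems-biology group would run on
such a cohort:

1. **Differential expression** — gene-wise Welch *t* on log2 expression,
   Benjamini–Hochberg correction, deterministic ranking.
2. **Co-expression modules (WGCNA-style)** — soft threshold β chosen by the
   scale-free fitting index R², unsigned adjacency `|cor|^β`, topological
   overlap TOM, average-linkage module detection, module eigengenes (first
   PC of the standardized module submatrix), and Pearson module–trait
   correlation with Student asymptotic *p*-values.
3. **Regulatory network inference (ARACNe-style)** — plug-in mutual
   information on copula-transformed expression, edge significance by
   exponential-tail extrapolation of a permutation null (default
   p = 1 × 10⁻⁷), data-processing-inequality pruning (tolerance 0.1), and a
   bootstrap consensus (default 100 resamples, support ≥ 0.5), restricted to
   candidate transcription factors.
4. **Driver ranking** — per-module regulatory score
   RS(tf) = Σ_targets w(tf,t)·|log2FC(t)|, with the top 1 % of TFs relative
   to each module's size flagged as candidate drivers.
5. **Drug repurposing** — connectivity-map scoring of an up/down signature
   against a perturbation database (KS enrichment of both tag sets,
   same-sign zeroing, extreme-based rescaling to [−1, 1]); profiles with
   score ≤ −0.60 are reversal candidates.
6. **Feature selection & classification** — mRMR (MID criterion), maximal
   information coefficient (MIC), and top-DEG lists intersected into a gene
   signature; stratified 5-fold × 10-repeat cross-validation with a native
   L2-logistic classifier (ROC AUC, accuracy), permutation importance,
   PCA and PLS-DA ordination.
7. **Validation statistics** — upper-tail hypergeometric overlap of DEG
   lists and single-sample GSEA (rank-weighted running sum, α = 0.25).
8. **Synthetic cohort generator** — a linear-Gaussian factor model that
   plants co-expression modules, TF→target regulation, group and subgroup
   shifts, trait couplings, functional readouts, and signature-reversing
   drugs among decoys, so that every stage has a ground-truth recovery test
   without any external data.

## Worked example

Recover the trait-linked modules and the planted reverser drugs from a
synthetic discovery cohort (47 AMI + 20 control samples, 2,000 genes):

```python
from macnet.simulate import SyntheticConfig, generate_cohort, generate_perturbation_db
from macnet.coexpression import pick_soft_threshold, detect_modules, module_trait_correlation
from macnet.diffexp import differential_expression
from macnet.repurposing import build_signature, connectivity_scores, candidate_filter

cohort = generate_cohort(SyntheticConfig(seed=1))
ami = cohort.meta.index[cohort.meta.group == "AMI"]
x_ami = cohort.expression[list(ami)]

beta = pick_soft_threshold(x_ami).chosen_power
modules = detect_modules(x_ami, beta)
mt = module_trait_correlation(modules, cohort.traits)
print(mt.sort_values("p").head(3).to_string(index=False))

de = differential_expression(x_ami, cohort.meta, ("Large", "Small"), column="subgroup")
sig = build_signature(de, modules, {"M4", "M5"})
db, reversers = generate_perturbation_db(cohort.config, sig, list(cohort.expression.index))
hits = candidate_filter(connectivity_scores(sig, db))
print(hits.head(4)[["drug", "s", "candidate"]].to_string(index=False))
print("planted reversers:", sorted(reversers))
```

Output:

```
module                trait         r            p        p_adj
    M4         infarct_size  0.747889 1.529152e-09 7.645758e-09
    M5    ejection_fraction -0.515031 2.120441e-04 1.060220e-03
    M3 end_diastolic_volume  0.421737 3.151947e-03 1.575974e-02
   drug         s  candidate
DRUG083 -1.000000       True
DRUG061 -0.990437       True
DRUG089 -0.980450       True
DRUG100 -0.240116      False
planted reversers: ['DRUG061', 'DRUG083', 'DRUG089']
```

Modules M4 and M5 are the detected counterparts of the planted
infarct-size-coupled (r target +0.6) and ejection-fraction-coupled
(r target −0.6) modules; all three planted reverser drugs are flagged at
connectivity score ≤ −0.60, with the strongest reversal scaled to exactly −1.

The same pipeline is scriptable from the shell (`macnet simulate`,
`macnet diffexp`, `macnet wgcna`, `macnet grn`, `macnet drivers`,
`macnet signature`, `macnet repurpose`, `macnet select`, `macnet classify`,
`macnet overlap`, `macnet ssgsea`, `macnet zscore`); every subcommand logs
its parameters and seeds to stderr and produces byte-reproducible output for
a fixed seed.

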