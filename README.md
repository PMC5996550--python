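# oligonet

Network-based prioritization of cancer gene candidates inside a recurrent
chromosomal co-deletion.

When two chromosome arms are lost together in most tumors of a cancer
type — as with the 1p/19q co-deletion that defines oligodendrogliomas —
hundreds of genes drop in copy number and expression at once, and
differential expression alone cannot tell drivers from passengers. This
package implements the alternative: learn gene regulatory networks from
paired expression and copy-number profiles, validate them against
degree-preserving random networks, then propagate each co-deleted gene's
influence through the networks onto cancer-relevant signaling and
metabolic pathway genes, and call *high-impact* genes whose pathway
influence significantly exceeds what the same gene achieves in randomly
rewired networks. Because real tumor cohorts are not redistributable, the
package ships a synthetic-cohort generator that emulates the study's
statistical structure (recurrent two-arm co-deletion in ~75% of tumors,
rarer whole-arm events, expression from a sparse signed network plus a
copy-number dose effect), so every stage is testable against known ground
truth. It is written for computational biologists studying dosage-driven
tumor development and for methodologists evaluating network-propagation
pipelines.

## The model

Each gene's expression is a sparse linear function of its own copy
number and of distant genes' expression,

    x_g = β₀ + β_cn · cn_g + Σ_r β_rg · x_r + ε,

with candidate regulators restricted to genes more than 50 positions away
in genome order (local neighbors would re-encode the shared copy-number
state). Predictors are selected along the LARS-lasso path under the
objective (1/(2n))‖y − Xβ‖² + λ‖β‖₁, each entry tested with the
covariance significance test (T = covariance gain at the entry knot /
σ̂²; p = exp(−T) under the asymptotic Exp(1) null), retained at
q ≤ 0.01, and refit without penalty. Ten networks are learned on
independent two-thirds training splits. Impacts then propagate through
M[t, r] = w_t · β_rt (w_t = held-out prediction quality of target t)
over all network paths, v = Σ_{k≤5} M^k e_source, and a source's total
impact on a pathway class, Σ_t |v_t|, is compared with its mean impact
under degree-preserving rewirings of each network by a paired one-sided
signed-rank test with q-value correction across sources.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the scaled
default cohort (300 genes, 120 tumors, 3 networks × 10 rewirings; config
in `configs/scaled_default.yaml`) and write everything to
`results/cohort_run/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_mutations_and_de.py
python analysis/03_infer_networks.py
python analysis/04_validate_and_score.py
python analysis/05_quantify_impacts.py
python analysis/06_benchmarks.py
```

Output of the first four steps (seed 1):

```
  tumors: 120 (90 co-deleted), normals: 3
  truth network: 321 edges, 77% activators
co-deleted tumors called: 90
rare-arm subcohorts (>=6 tumors): {'4q_del': 8, '13q_del': 11, '15q_del': 8, '18q_del': 17, '7q_dup': 8}
DE [codeletion]: 115 under- / 6 overexpressed (q<0.05); 69 sources in mutated region
network 0: 80 train / 40 test, 506 edges, 73% activators
held-out median correlation: 0.881 (random networks: 0.462)
one-sided rank-sum p vs random: 1.11e-103
```

Reading this: the mutation caller recovers all 90 simulated co-deletion
carriers from the data alone and finds five rare-arm subcohorts with at
least six tumors; most co-deleted genes are down-regulated (115 under-
vs 6 overexpressed at q < 0.05), and 69 differentially expressed genes
inside the co-deleted region become candidate sources. The learned
networks predict held-out tumors far better than their degree-preserving
rewirings (median per-gene correlation 0.88 vs 0.46), which is the
evidence that the edges carry real predictive structure. At this
demonstrative 3-network scale the paired impact test cannot reach
q ≤ 0.05 (its exact p floor is 1/8), so step 05 reports empty high-impact
lists; `analysis/06_benchmarks.py` runs the 10-network planted-driver
benchmark, where sources wired into pathway genes are flagged while
isolated passengers rank far below them, plus the edge-recovery and
calibration benchmarks. The same stages are scriptable via the `oligonet`
CLI (`oligonet run --config ... --outdir ... [--resume]`).

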