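# glyconet

Inference of enzymatic reactions in the human IgG glycosylation pathway
from glycomics abundance data.

## The problem

The Fc domain of immunoglobulin G carries a glycan built by four
glycosyltransferases (B4GalT1, ST6Gal1, FUT8, MGAT3), each adding one
sugar unit per reaction. Which substrate each enzyme accepts in vivo is
only partially known, and direct subcellular measurement is out of
reach. `glyconet` infers reactions statistically: in a Gaussian
graphical model (GGM) estimated from population glycomics data —
partial correlations between glycoform abundances, conditioned on all
other glycoforms plus age and sex — strong edges concentrate between
glycans one enzymatic step apart. Edges that the known pathway cannot
explain then point to missing reactions, which are proposed as *rules*
(new substrate specificities) and scored against the data.

The package is aimed at computational glycobiologists and statistical
omics analysts working with IgG Fc glycopeptide panels (IgG1, IgG2/3,
IgG4 subclasses), but the machinery — shrinkage GGM estimation,
pathway-distance enrichment, rule-based model search — applies to any
panel with a single-addition reaction grammar.

## Method in brief

For glycoform pairs (i, j), the shrinkage partial correlation is
obtained from the inverse of R* = (1 − λ\*) R + λ\* I, with the analytic
intensity λ\* = Σ V̂ar(r_ij) / Σ r_ij²; edges are kept at a
Benjamini–Hochberg FDR of 0.01 and additionally masked by Pearson
significance. The overlap of a candidate pathway model M with the GGM is
scored by a two-sided Fisher exact test on

|                | significant | not significant |
|----------------|-------------|-----------------|
| distance = 1   |      a      |        b        |
| distance > 1   |      c      |        d        |

where distance is the shortest undirected path in M's reaction graph.
All 2⁶ = 64 models generated by six candidate rules are fitted; 95%
bootstrap confidence intervals over the full pipeline decide whether a
model beats the known pathway, and the simplest winning model is
selected. Subclass modularity (Newman's Q for the fixed subclass
partition, against a degree-preserving rewiring null) and cross-cohort
replication tests quantify network structure; product–substrate ratio
traits with the p-gain statistic connect predicted reactions to genetic
association evidence.

## Worked example

Simulate a cohort whose conditional-dependence structure is the known
pathway extended with rules G1 (galactosylation of sialylated glycans)
and N2 (bisection of galactosylated, fucosylated glycans), then run the
full pipeline:

```python
import numpy as np
from glyconet import (SimulationConfig, simulate_cohort, preprocess_pipeline,
                      ggm, known_pathway, default_rules, extend_model,
                      fit_and_select, rewire_null)

rules = {r.id: r for r in default_rules()}
known = known_pathway()
truth = extend_model(known, [rules["G1"], rules["N2"]])

matrix, _ = simulate_cohort(SimulationConfig(model=truth, seed=1))
clean, info = preprocess_pipeline(matrix)          # PQN + log, per subclass
pearson, partial, g = ggm(clean.values, clean.covariates, alpha=0.01)
mod = rewire_null(g, n_null=999, seed=1)
fits, selected = fit_and_select(clean.values, known, list(rules.values()),
                                clean.covariates, n_boot=200, seed=1)
```

Output for this seed:

```
retained 700 of 700 samples
Pearson edges: 989
partial edges: 86  (lambda* = 0.012)
GGM edges: 84
subclass modularity Q = 0.255, empirical p = 1.00e-03
known pathway:  p = 7.22e-32  95% CI [6.0e-32, 1.3e-21]
selected model: G1+N2  p = 2.75e-48  95% CI [3.5e-46, 1.1e-33]
```

Reading the numbers: of 1225 glycoform pairs, 86 partial correlations
survive FDR control and 84 also pass the Pearson mask — the GGM. The
positive-edge network is modular with respect to the IgG subclasses
(Q = 0.255; none of 999 degree-preserving rewirings reached the observed
Q, so the empirical p is at its floor of 1/1000). The known pathway
already explains most edges (Fisher p = 7.2 × 10⁻³²), but the model
extended with rules G1 + N2 explains them better (p = 2.7 × 10⁻⁴⁸) with
non-overlapping bootstrap intervals, so the selection returns exactly
the planted rule set.

The same pipeline is available from the shell:

```bash
glyconet simulate --n 700 --seed 1 --out sim/
glyconet run --input sim/cohort.csv --covariates sim/covariates.csv \
             --bootstrap 200 --nulls 999 --seed 1 --out results/
```

## Layout

* `src/glyconet/pathway.py` — glycan grammar, reactions, rules, pathway
  models and distances; fixtures in `src/glyconet/data/`
* `src/glyconet/preprocess.py` — PQN, log transform, missingness and
  kinship filters
* `src/glyconet/netinfer.py` — Pearson and shrinkage partial-correlation
  networks, FDR masks, GGM, consensus
* `src/glyconet/modularity.py` — subclass modularity and rewiring null
* `src/glyconet/inference.py` — pair classification, Fisher overlap,
  bootstrap model fitting, parsimony selection, replication test
* `src/glyconet/ratios.py` — product–substrate ratio traits, p-gain,
  additive association
* `src/glyconet/synth.py` — synthetic cohort generator with stored truth
* `src/glyconet/cli.py` — `glyconet` command-line interface

See `docs/methods.md` for the full statistical documentation.
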