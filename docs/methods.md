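# Methods

`glyconet` infers enzymatic reactions in the IgG Fc N-glycosylation
pathway from population-scale glycomics abundance tables. This note
documents the statistical model, the pathway encoding, the synthetic
cohort generator and the numerical choices behind them.

## The pathway model

IgG Fc glycans are biantennary complex-type structures described by four
features: number of galactoses (0–2, added by B4GalT1), number of sialic
acids (0–2, added by ST6Gal1 onto galactoses, hence `sia <= gal`), core
fucose (FUT8) and bisecting GlcNAc (MGAT3). A reaction is a single-sugar
addition between two structures; the *known pathway* ships as a versioned
JSON fixture (`glyconet/data/known_pathway.json`) with a panel of 21
structures (20 measured per IgG1/IgG2; 10 fucosylated structures for
IgG4; G1FNS1 present as an unmeasured intermediate) and 20 reactions. In
the encoded known pathway, core fucosylation acts only on the
agalactosylated, unbisected core (G0); bisection only before
galactosylation (G0, G0F); galactosylation on all non-sialylated
structures; and sialylation on every galactosylated structure.

*Pathway distance* between two structures is the shortest-path length on
the reaction graph treated as **undirected**: distances are needed
between structures that do not lie on a common directed path (e.g., two
products of a branching substrate), which forces the undirected
convention. Only path lengths are used, so tie-breaking among shortest
paths is irrelevant.

Candidate reactions — single additions over the panel absent from the
known pathway (18 of them) — are grouped into six *rules* by enzyme and
substrate features (`glyconet/data/rules.json`):

| rule | enzyme  | substrate predicate                      | members |
|------|---------|------------------------------------------|---------|
| F1   | FUT8    | galactosylated, unbisected, unsialylated | 2       |
| F2   | FUT8    | bisected                                 | 3       |
| F3   | FUT8    | sialylated, unbisected                   | 3       |
| G1   | B4GalT1 | sialylated                               | 3       |
| N1   | MGAT3   | galactosylated, non-fucosylated          | 2       |
| N2   | MGAT3   | galactosylated, fucosylated              | 5       |

The F1 predicate excludes sialylated substrates so the three FUT8 rules
partition the fucosylation candidates (F3 owns the sialylated ones); the
six rules together partition the full candidate set, a property the test
suite asserts. The 2^6 = 64 rule subsets define the candidate pathway
models; adding G1 + N2 to the known pathway introduces 8 reactions.

## Preprocessing

Samples with missing values are dropped; related samples are removed
given a kinship matrix using the 0.0312 threshold (first-degree cousins
or closer). Relatedness filtering is greedy hub-removal: repeatedly drop
the sample involved in the most above-threshold pairs (ties: lowest
sample id) until no violating pair remains — this approximates the
minimum vertex cover and retains the most samples. Probabilistic
quotient normalization is applied per IgG subclass: the reference is the
per-glycoform median over all retained samples (i.e., computed after the
sample filters), each sample's dilution factor is the median of its
quotients against the reference. Abundances are then natural-log
transformed; the log base only rescales columns and leaves every
correlation unchanged. Batch effects, when batch labels are supplied,
are handled by a simple per-batch median/MAD location-scale adjustment
on the log scale — a transparent, rank-light adjuster, not an
empirical-Bayes method.

## Network estimation

Pearson networks use product–moment correlations with exact t-based
p-values (df = n − 2). Partial correlations use a Schäfer–Strimmer-style
shrinkage estimator: the sample correlation matrix is shrunk toward the
identity with the analytic intensity
λ\* = Σ<sub>i≠j</sub> V̂ar(r<sub>ij</sub>) / Σ<sub>i≠j</sub> r<sub>ij</sub>²
(clipped to [0, 1]), inverted, and rescaled to partial correlations.
λ\* > 0 keeps the matrix invertible even with p close to n. Age and sex
enter the estimation as extra columns and are removed from the returned
network, so every reported coefficient is conditioned on them.

Edge significance (default) uses the Fisher z-transform with effective
degrees of freedom n − k − 2 − c for a partial correlation of order
k + c (k conditioned glycoforms, c confounders). An *empirical-null*
mode is provided for parity with GeneNet-style analyses: the null
density f₀(r; κ) ∝ (1 − r²)^((κ−3)/2) — equivalently r² ~ Beta(1/2,
(κ−1)/2) — is fitted to all coefficients by maximum likelihood
(treating the edge population as predominantly null) and p-values are
its tail areas. The two modes can differ by a few edges at a fixed FDR;
this matters when comparing edge counts against analyses that used the
empirical null.

Benjamini–Hochberg FDR control at α = 0.01 is applied over all glycoform
pairs within each network kind. The final GGM keeps a partial-correlation
edge only where the Pearson correlation is also significant; negative
significant edges are retained in the network object (and count as
significant in the overlap tables by default, switchable), but only
significantly **positive** edges enter the modularity analysis.

## Modularity

Newman's Q is evaluated for the fixed IgG-subclass partition (no
community optimization): Q = Σᵢ (eᵢᵢ − aᵢ²) over the positive-edge
subgraph, together with the row-normalized cross-subclass edge-fraction
("relative out-degree") matrix. Significance comes from degree-preserving
double-edge-swap rewiring: 10 × |E| *accepted* swaps per null network
(rejected swaps — self-loops or multi-edges — are re-drawn and do not
consume the budget), 10⁵ null networks by default, and the empirical
p-value uses the +1 correction, p = (1 + #{Q₀ ≥ Q}) / (B + 1), so a
bound like p < 10⁻⁵ is reportable but p = 0 is not.

## Overlap scoring and model selection

Glycoform pairs are classified against a pathway model: within-subclass
pairs get the structure-graph distance; same-structure cross-subclass
pairs are labeled "X" (they share no enzymatic step — the glycans sit on
different proteins) and excluded, as are all remaining cross-subclass
pairs. The overlap of a model with the GGM is scored by a two-sided
Fisher exact test on the 2×2 table (distance = 1 vs. > 1) × (significant
vs. not). The same structure graph serves all subclasses; IgG4 pairs
involving unmeasured structures are simply absent.

Model uncertainty: nonparametric bootstrap (default 10,000 resamples)
re-running the entire pipeline — shrinkage estimation, FDR masks, GGM
masking, classification, Fisher test — per resample, then percentile
95% intervals (the plain percentile method; nothing in the procedure
requires bias correction, and the interval is interpreted loosely as a
sampling band for a statistic used as an effect-size score). A model
beats the known pathway when its point p-value is lower *and* the two
intervals do not overlap; among all models that beat it, the one with
the fewest rules wins, ties broken by the lower point p-value. Inside
the bootstrap loop the two-sided Fisher p is computed directly from the
hypergeometric pmf over the table support; this path is cross-checked
against `scipy.stats.fisher_exact` and an exhaustive enumeration oracle
in the tests.

Replication across cohorts: a consensus network counts, per edge, the
cohorts in which it is significant; an edge is *replicated* when
significant in all. The replication Fisher test crosses replication
status with distance = 1 over the pairs significant in at least one
cohort.

## Ratio traits and p-gain

For every reaction with both endpoints measured in a subclass, the trait
is log(product/substrate), residualized on age and sex by OLS and then
rank-based inverse-normal transformed (Blom offsets) — residualization
first, transform second. The fixture yields 47 such traits for the known
pathway and 83 for the full single-addition sketch. The p-gain of a
ratio association is min(p_substrate, p_product) / p_ratio, with ≥ 10
(one order of magnitude) flagged as meaningful. The genome-wide
threshold is 5 × 10⁻⁸ Bonferroni-divided by the number of ratio traits
tested; it is computed from the trait count, not hard-coded (for 95
traits it equals 5.26 × 10⁻¹⁰). A minimal additive association (slope
test of trait on allele dosage) is included so the ratio/p-gain plumbing
is testable on synthetic genotypes; genome-scale association analysis is
out of scope.

## Synthetic cohorts

The generator plants a Gaussian graphical model equal to a chosen
pathway model: precision matrix with unit diagonal, −ρ on reaction edges
within each subclass block and −ρ<sub>x</sub> on same-structure
cross-subclass pairs. Because the diagonal is 1, the planted partial
correlation of each edge equals ρ exactly, and negative precision
off-diagonals yield the positive partial correlations observed in real
glycomics networks. Positive definiteness is enforced *spectrally*: the
coupling matrix C is scaled by 0.99/λ_max(C) only when I − C is not
already positive definite. This minimal scaling was chosen over
diagonal-dominance scaling because the latter would silently shrink the
planted effect from ρ to roughly ρ/(1 + max row sum) (≈ 0.35 → 0.13 on
this pathway), divorcing the configured study condition from the
generated data. A consequence worth knowing: a *uniform* edge partial
correlation is only feasible up to 1/λ_max of the coupling pattern —
about 0.26 for the G1+N2-extended pathway — so configurations above
that bound are attenuated to ≈ 0.23 effective strength, and the
generator's truth record stores the attenuated matrix.

On top of the latent Gaussian (marginal log-scale SD 0.30), the
generator layers per-glycoform baseline offsets, an age effect
(default 0.01 per year, signed so galactosylation/sialylation decline
with age), a sex effect (0.10, on fucosylated structures), exponentiates
to give log-normal abundances, multiplies each sample by a log-normal
dilution factor (σ = 0.30) and applies optional missingness. Defaults
emulate the discovery-cohort setting (n = 700 after filtering). What the
generator does *not* emulate: compositional closure of normalized MS
data (real Pearson coefficients center near zero; simulated ones are
predominantly positive), batch structure, heteroskedastic measurement
noise, and genuine kinship. Pipeline tests on this generator therefore
demonstrate statistical correctness of the machinery, not robustness to
every artifact of real LC-ESI-MS data.

Two test-design notes. PQN factor recovery is verified in the
dilution-dominated regime the method was designed for (no planted
network, weak residual variation): with strong biological covariation a
median quotient necessarily absorbs the common mode, and no normalization
can split that from dilution, so near-perfect recovery is only a fair
demand when dilution dominates. Second, the end-to-end selection
exercise (simulate under G1+N2, recover {G1, N2}) sits exactly at the
feasibility boundary described above: at the attenuated edge strength
the pipeline recovers {G1, N2} in roughly 60% of replicates at 200
bootstrap resamples and otherwise conservatively returns the known
pathway (it never selects a wrong extension; the specificity control
under the known-pathway truth selects no extension).

## Problem sizes used in the test suite

Simulation-based tests use n = 500–1000 samples, 50 glycoforms,
bootstrap sizes of 30–200 and 10²–10³ rewiring nulls; the rewiring and
bootstrap defaults for real analyses (10⁵ nulls, 10⁴ resamples) are CLI
defaults, not test settings. The end-to-end selection test runs 50
replicates at n = 700 with 200 bootstrap resamples.

## Known limitations

* The empirical-null mode approximates GeneNet's null fit; exact edge
  counts at a fixed FDR can differ by a few edges from analyses using
  the original implementation.
* The subclass panel and reaction fixture are a transcription of the
  standard IgG Fc glycopeptide panel; laboratories quantifying different
  glycoform sets should supply their own pathway JSON.
* Ratio traits are defined only where both endpoints are measured in a
  subclass; reactions through unmeasured intermediates produce no trait.
* Model selection compares marginal bootstrap intervals; a paired
  comparison (or likelihood-based selection via AIC/BIC) would be more
  powerful and is deliberately out of scope.
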