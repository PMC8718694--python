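# wcflux

Interpretation of metabolic reaction-flux time series from whole-cell-model
gene-knockout simulations.

Whole-cell models simulate every cellular process over a cell cycle and
emit a flux trajectory for each metabolic reaction — thousands of long,
wildly heterogeneous time series per simulated genotype.  `wcflux` turns
that output into interpretable structure for systems biologists studying
gene essentiality and genome design: which reactions leave their wild-type
behavioural range after a knockout, how those abnormality fingerprints
cluster by phenotype, and which reactions in the metabolic network are
markers of a phenotypic class.

## The method

For each reaction flux series *y(t)* the pipeline extracts four regression
features — the intercept β₀ and gradient β₁ of the least-squares fit
*y = β₀ + β₁t*, the coefficient of determination R², and the mean squared
residual — and reduces each reaction's feature set to two principal
components.  Three boundaries around the wild-type scores (extrema, 99%
and 95% per-axis percentile boxes) act as weak labelling functions; their
votes are combined into probabilistic normal/abnormal labels, on which one
four-hidden-layer perceptron per reaction is trained (epochs × batch ×
width grid of {5,10,15} × {50,100,150} × {750,1500,2250}; networks under
70% holdout accuracy are dropped).  Each simulation then becomes a binary
**flux profile** over the retained reactions, visualised by PCA.

On the network side, the stoichiometric matrix **S** yields the reaction
adjacency **A** = SᵀS (binarised, zero diagonal): reactions are adjacent
when they share a metabolite.  **Driver nodes** — the reactions that must
be controlled to control the network — are the nodes left unmatched by a
(maximum or greedy) matching.  Wild-type abnormality frequencies are
fitted with an exponential distribution whose 95% quantile
−ln(0.05)·mean separates stochastic flicker from consistently abnormal
behaviour.  Each driver reaction is tested as a phenotype marker: a linear
SVM on the 2-D profile scores (> 95% training accuracy ⇒ linearly
separable) and the phi coefficient
φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)) against every phenotype class.

A synthetic-data generator (steady / ramping / oscillating / stepping /
bursting archetypes, per-simulation parameter jitter, knockout
perturbations with known ground truth) makes every stage testable without
the original multi-hundred-gigabyte simulation archive.  See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Generate a synthetic study (12 reactions; 30 wild-type simulations; three
knockout genotypes × 25 simulations with the metabolic class perturbing
reactions R_0000–R_0005, the RNA class R_0000–R_0002, and a non-essential
class left untouched), then run the eight-stage pipeline:

```sh
wcflux simulate -o demo --seed 7
wcflux run-all -c demo/config.yaml
```

```
done; see demo/results/manifest.json
  features: ok (1260 records)
  weak_labels: ok (1260 records)
  classifiers: ok (12 records)
  profiles: ok (105 records)
  profile_pca: ok (75 records)
  network: ok (14 records)
  markers: ok (2 records)
```

1260 = 105 simulations × 12 reactions feature fits and weak labels; all 12
per-reaction classifiers were retained; 105 binary flux profiles were cut,
and the 75 knockout profiles reduced to two principal components.  The
reaction graph has 14 nodes (12 reactions + 2 transporters), and the
marker stage reports the two driver nodes (`demo/results/markers.tsv`):

```
reaction_id  pathways  separability_accuracy  separable  best_class     best_phi
R_0001       n/a       1.0                    True       non_essential  1.0
R_0003       n/a       1.0                    True       metabolic      -1.0
```

R_0001 is perturbed in both knockout classes, so its *normal* behaviour
perfectly tags the non-essential simulations (φ = 1); R_0003 is perturbed
only in the metabolic class, so its *abnormal* behaviour tags that class
(φ = −1 under the normal-row table orientation) and both split the profile
PCA plane with 100% linear-SVM accuracy.  Every artifact is TSV (plus a
GraphML reaction graph), and `demo/results/manifest.json` records
versions, seed, config hash and per-stage counts;
`wcflux report -o demo/results` reprints it.

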