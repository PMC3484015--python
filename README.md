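# nucrank

Ranked retrieval of segmented nuclei and EDT-based radial gene-position
analysis for fluorescence microscopy.

## The problem

Quantifying *gene repositioning* — whether a FISH-labelled gene locus
sits closer to the nuclear centre or periphery in diseased tissue —
requires hundreds of accurately segmented nuclei per sample.  Automated
segmentation of DAPI-stained tissue (clumped cells, debris, background
fluorescence, sectioning artifacts) produces a large surplus of
*candidate* objects of which only a minority are usable single nuclei.
`nucrank` performs **segmentation assessment**: it judges each candidate
at the object level and ranks the population so that downstream
position measurements use only well-segmented nuclei.

It is written for image-analysis practitioners who already have a
segmentation pipeline (any algorithm — the package consumes label
masks) and need an automated, calibrated quality screen plus the radial
gene-position statistics that follow.

## The method

**Ranking.** Shape, texture and FISH-spot features x₁…x_m are extracted
per candidate, and a logistic regression models the log-odds that the
candidate is a well-segmented nucleus:

    ln p̂ / (1 − p̂) = α + β₁x₁ + … + β_m x_m
    p̂ = e^(α+βᵀx) / (1 + e^(α+βᵀx))

Reviewer labels (good = 1, maybe = 0.5, reject = 0) are averaged into a
fractional target in [0, 1] and the fit maximises the Bernoulli-form
likelihood Σ [y ln p̂ + (1−y) ln(1−p̂)], so p̂ is a *calibrated*
posterior: sorting on it gives a ranked list, thresholding it (the
default screen keeps p̂ > 0.1) selects usable nuclei, and its mean over
a tissue core or subject, (1/N) Σ_{i∈S} p̂ᵢ, is a **dataset-quality
score** in [0, 1] estimating the yield of usable nuclei.

**Gene centrality.** For a spot x inside a nucleus with contour C and
interior M:

    edt(x)  = min_C d(x, C)                 (0 on the boundary)
    nedt(x) = 1 − edt(x) / max_M edt        (0 at the centre, 1 at the periphery)
    cedt(x) = P( nedt(M) ≤ nedt(x) )        (empirical CDF over the interior)

cEDT is scale- and shape-invariant: uniformly placed spots have uniform
cEDT whatever the nuclear outline, so distributions pool across nuclei
of different size and shape.  A sample's pooled per-gene cEDT
distribution is compared to a pooled normal control with the two-sample
Kolmogorov–Smirnov test at α = 0.01.

**Synthetic cohorts.**  Because no public dataset accompanies the
method, `nucrank.synthgen` generates seeded cohorts — DAPI-like rough
ellipses with chromatin texture, candidate masks degraded by a
controlled failure taxonomy (boundary jitter, merges, fragments,
border clipping, debris) with derived quality labels, and FISH spots
placed at a prescribed Beta radial law — so the entire pipeline is
testable end to end.

## Worked example

```python
import numpy as np
from nucrank import synthgen, features, ranking, centrality

spec = synthgen.SynthesisSpec(n_subjects=2, cores_per_subject=2, seed=7)
cohort = synthgen.generate_cohort(spec)

table = features.extract_all(cohort.candidates_by_image(),
                             cohort.images_by_id(),
                             cohort.assigned_spots())
X = table.set_index("object_id")
y = cohort.labels().reindex(X.index)
prov = cohort.provenance().set_index("object_id").reindex(X.index)

folds, summary = ranking.loso_evaluate(X, y, prov["subject_id"],
                                       prov["core_id"], seed=7)
print(f"LOSO over {summary['n_folds']} cores: "
      f"mean ROC {summary['mean_roc']:.3f} "
      f"(min {summary['min_roc']:.3f}, max {summary['max_roc']:.3f})")

model = ranking.fit_logistic(X, y, seed=7)
post = ranking.predict_posterior(model, X)
for core, grp in prov.groupby("core_id"):
    q = ranking.dataset_quality(post.loc[grp.index], scope=core)
    print(f"quality[{core}] = {q.value:.3f}  ({q.n} candidates)")

ranked = ranking.rank_candidates(post)
selected = ranking.select_usable(ranked, ("threshold", 0.1))
print(f"{len(selected)}/{len(ranked)} candidates pass the 0.1 screen")

sel = [o for o in cohort.all_candidates() if o.object_id in set(selected)]
dists = centrality.gene_position_distribution(sel, cohort.assigned_spots(),
                                              sample_id="S01+S02")
for gene, d in sorted(dists.items()):
    print(f"{gene}: {d.n} spots, median cEDT {np.median(d.cedt):.3f}")
```

Output:

```
LOSO over 4 cores: mean ROC 0.954 (min 0.917, max 1.000)
quality[S01C01] = 0.437  (24 candidates)
quality[S01C02] = 0.302  (31 candidates)
quality[S02C01] = 0.246  (28 candidates)
quality[S02C02] = 0.164  (32 candidates)
42/115 candidates pass the 0.1 screen
FRA2: 82 spots, median cEDT 0.470
HES5: 79 spots, median cEDT 0.505
```

Each leave-one-subject-out fold trains the ranking on the other
subject's annotated candidates and scores the held-out core, so the
mean ROC (0.954 here) measures retrieval of well-segmented nuclei on
unseen tissue.  The quality scores are the mean posterior per core —
low values flag cores where more images would be needed.  The final
lines are the pooled radial position distributions of the two labelled
genes measured on the screened nuclei only (mid-radial placement, as
this generator prescribes Beta(2, 2)).

## Command line

The same pipeline is scriptable stage by stage:

```sh
nucrank simulate --seed 3 --out-dir cohort/
nucrank extract --data-dir cohort/ --out features.csv
nucrank fit --features-csv features.csv --annotations ann.csv --model-out model.json
nucrank rank --features-csv features.csv --model model.json --out ranking.csv
nucrank quality --ranking-csv ranking.csv --features-csv features.csv --out quality.json
nucrank centrality --data-dir cohort/ --ranking-csv ranking.csv --out centrality.csv
nucrank compare --test-csv t.csv --control-csv c1.csv --control-csv c2.csv --gene FRA2 --out cmp.json
nucrank evaluate-loso --features-csv features.csv --labels-csv cohort/truth_labels.csv --out loso.csv
nucrank evaluate-trainsize --features-csv features.csv --labels-csv cohort/truth_labels.csv --out curve.csv
```

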