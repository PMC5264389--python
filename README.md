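# odorhab

Tools for asking whether we habituate differently to different odorants,
and which molecular and perceptual properties of a smell drive that
difference.

Olfactory habituation is the perceptual fading of an odor's intensity
during continuous stimulation. Given continuous 0–100 intensity ratings
(4 Hz, 120 s, 481 samples per curve) from a panel of subjects smelling a
set of odorants, the package

1. **screens the recordings** with three exclusion rules — subjects who
   missed sessions, subjects whose traces alternate chaotically (tracking
   breathing rather than perception), and individual curves whose response
   delay exceeds 17 s — then anchors every retained curve at 1.0 by
   dividing by its first sample;
2. **clusters** the normalized curves with squared-Euclidean k-means
   (k = 3, chosen by mean silhouette) and labels the centroid curves
   low / mid / high habituation by terminal intensity;
3. **embeds each odorant in a habituation space**: the per-odorant median
   of city-block distances d(curve, centroid) = Σₜ |I(t) − C(t)| to the
   three labelled centroids (a large coordinate = low similarity to that
   habituation profile);
4. **tests odorant differences** in each coordinate with a linear mixed
   model (odorant fixed, subject random intercept), omnibus Wald F and
   all-pairs contrasts with Benjamini–Hochberg FDR control;
5. **ranks the determinants of habituation** with a from-scratch
   multi-response PLS (kernel algorithm): X holds 15 explanatory variables
   per odorant (8 molecular descriptors, 4 sensory means, and 3
   categoricals expanded into a level-rescaled disjunctive table — 33
   columns), Y the three habituation coordinates; components are chosen by
   leave-one-out RMSEP, and predictors are ranked by VIP
   (VIPⱼ = √(p · Σₐ SSₐ wⱼₐ² / Σₐ SSₐ), with VIP > 1 deemed important).

Because the original rating data were never released, the package ships a
synthetic-cohort generator with known ground truth (decay curves
I(t) = L·[p + (1−p)·e^(−λ(o)t)] + ε, with log λ linear in autoscaled
descriptors) plus the published 32-odorant descriptor panel, so every
stage is testable end to end. It is aimed at psychophysicists and
chemometricians who want a reproducible QSOR-style habituation pipeline
or a harness for method experiments on rating time series.

## Worked example

```python
from odorhab import (
    generate_cohort, default_config, default_truth, apply_exclusions,
)

curves, ratings, truth = generate_cohort(default_config(), default_truth(seed=1))
retained, report = apply_exclusions(curves)
print("input curves:   ", report.n_input_curves)
print("chaotic excluded:", report.n_chaotic_excluded)
print("delayed excluded:", report.n_delay_excluded)
print("retained:       ", report.n_retained)
```

```
input curves:    1808
chaotic excluded: 160
delayed excluded: 69
retained:        1531
```

The default cohort mirrors the study design — 58 recruited subjects, 3 of
whom miss sessions, 5 chaotic raters, and 69 curves with a response delay
over 17 s — so the exclusion stage retains exactly 1531 of the curves, the
5 chaotic subjects losing all 32 trials each.

The full pipeline (`odorhab run --seed 1 --out run/`, or
`run_pipeline(PipelineConfig(...))` from Python) chains
preprocess → clustering → mixed models → design matrices → PLS and writes
every intermediate as CSV plus a `manifest.json`. On the default cohort it
reports a 32×33 X matrix and a VIP ranking of the determinants:

```
     variable      vip  component less_habituation_when
 pleasantness 1.726351          1             increases
           mw 1.722146          1             increases
          oav 1.699932          1             decreases
    intensity 1.691679          1             decreases
trigeminality 1.624426          1             decreases
           vp 1.585868          1             decreases
```

Read each row against the generator's truth: the default synthetic truth
makes vapour pressure raise the decay rate (β(vp) > 0), so odorants rich
in vp habituate *more* — i.e. habituation is lower when vp decreases,
exactly what the report prints. The `component` column is the latent
component where the variable contributes most of its explained variance.

Stage-wise subcommands (`odorhab simulate | preprocess | cluster |
regress | report`) run each step standalone on the previous step's CSVs.

## Layout

- `src/odorhab/datasets.py` — packaged 32-odorant descriptor table; synthetic OAV and session assignment
- `src/odorhab/simulate.py` — cohort generator with known ground truth
- `src/odorhab/preprocess.py` — parsing, exclusion rules, normalization
- `src/odorhab/cluster.py` — `CurveKMeans`, silhouette, centroid labels, habituation space
- `src/odorhab/mixed.py` — subject-random-intercept models, FDR pairwise tests
- `src/odorhab/design.py` — X/Y assembly, disjunctive coding, autoscaling
- `src/odorhab/pls.py` — `KernelPLS`, LOO RMSEP, explained variance, VIP, interpretation
- `src/odorhab/pipeline.py`, `cli.py` — orchestration and the `odorhab` command

See `docs/methods.md` for the model, the numerical choices, and what the
synthetic cohorts do and do not emulate.
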