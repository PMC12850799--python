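# ccegrade

Bowel-cleansing quality grading for colon capsule endoscopy (CCE), and the
agreement analysis between an automated per-frame grader and human readers.

## The problem

A swallowed capsule camera records a video of the colon. Whether that video
is diagnostically usable depends on bowel-cleansing quality, traditionally
graded by human readers on the qualitative 4-point Leighton-Rex scale
(poor, fair, good, excellent) per colon segment, dichotomized to
*nonacceptable* (poor) vs *acceptable* (fair/good/excellent), with the whole
examination acceptable only if **every** segment is. Human grading is slow
and subjective; an automated grader scores every frame instead. The question
this package operationalizes: when the frame-score distribution of a video
is summarized by a single statistic and mapped back to the Leighton-Rex
scale, how well does the result agree with the human readers — and which
summary statistic agrees best?

## The pipeline

1. **Frame scoring** (`frame_scoring`): each pixel of a frame is labelled
   clean or dirty (a configurable HSV-threshold rule: dirty = yellow/brown
   hue at sufficient saturation and brightness); the frame's clean fraction
   `f` maps to a continuous rating `r = 1 + 4f` on `[1, 5)`.
2. **Sequence grading** (`sequence_grading`): a video's rating stream is
   summarized by mean, median, quartiles (Q1, Q3) and the 2nd/98th
   percentiles; each statistic floors (`⌊·⌋`) to a Leighton-Rex grade and
   dichotomizes to the 2-point scale.
3. **Colon model** (`colon_model`): reader-supplied flexure timestamps cut
   the stream into right-sided, transverse and left-sided colon (half-open
   frame intervals); readers' five segment grades merge to three by
   worst-of-pair; overall grade = minimum over segments.
4. **Agreement** (`agreement`): algorithm-vs-reader pairs are
   cross-tabulated; percent agreement, Cohen's κ = (p_o − p_e)/(1 − p_e)
   for the binary scale and weighted κ (linear Cicchetti–Allison weights by
   default, quadratic optional) for the ordinal scale, with
   Fleiss–Cohen–Everitt asymptotic standard errors, 95% CIs, a bootstrap
   cross-check, and the standard interpretation ladder
   (κ ≤ .20 "None" … > .90 "Almost perfect").
5. **Synthetic data** (`synthetic_data`): seeded generators for frames with
   exact ground-truth dirt masks, per-video rating streams around latent
   segment grades, and reader reports drawn through a confusion matrix —
   including a preset calibrated to the real cohort's marginal rates.
6. **Orchestration** (`pipeline_io` + `ccegrade` CLI): YAML config, CSV/JSON
   I/O, the end-to-end `run_study`, and rendering to Markdown/CSV tables.

## Worked example

```python
import numpy as np
from ccegrade import build_contingency, cohen_kappa

# Overall acceptability of 842 videos, algorithm (mean statistic) vs readers:
# 26 both-nonacceptable, 24 algorithm-only, 196 reader-only, 596 both-acceptable.
pairs = [(1, 1)] * 26 + [(1, 2)] * 24 + [(2, 1)] * 196 + [(2, 2)] * 596
res = cohen_kappa(build_contingency(pairs, k=2))
print(f"kappa {res.kappa:.2f} ({res.ci95[0]:.2f}-{res.ci95[1]:.2f}), "
      f"agreement {res.percent_agreement:.1f}%, label {res.label}")
```

prints

```
kappa 0.10 (0.05-0.16), agreement 73.9%, label None
```

73.9% of videos get the same binary call, yet κ is only .10: with 73.6% of
reader calls acceptable and 94.1% of algorithm calls acceptable, most of
that raw agreement is expected by chance — the lenient algorithm calls 23%
of videos acceptable where the conservative readers do not.

An end-to-end run on a synthetic cohort:

```bash
ccegrade run-all --out scratch/demo --n-videos 100 --seed 0
```

The numbered drivers under `analysis/` narrate the same sequence at study
scale (simulate 842 videos → score frames → grade videos → agreement study
→ published-table reproduction), writing their tables under `results/`.

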