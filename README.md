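# stentmorph

Quantitative morphology of ureteral stents on serial radiographs.

After a double-J ureteral stent is placed, the obstructed ureter decompresses
and the stent visibly *straightens* on follow-up X-ray — a cue clinicians read
qualitatively when deciding whether the stent can come out. `stentmorph`
turns that impression into numbers: it extracts the stent centerline from a
binarized region of interest (ROI) and scores its curvature with two metrics,
then compares paired insertion/follow-up cohorts statistically. Because
clinical radiograph sets of this kind are access-restricted, the package
ships a synthetic phantom generator with exact ground truth, used for all
validation.

## The measurements

Given a binary stent mask, the pipeline traces the outer contour of the
largest 8-connected component, collapses it to a single-valued curve
`x(t)` — the median lateral (column) coordinate of the contour on each axial
row `t` — and trims 5% of the points at each end to discard the pigtail
loops. Two statistics are computed per image:

* **Segment vector angles.** The centerline is split into `k = 100`
  contiguous segments; each segment gets the unit direction vector `v_i` of
  its total-least-squares line fit, and the angle between vectors is
  `θ = acos(v_i · v_j) · 180/π` (a dot product outside `[-1, 1]` from
  floating-point overshoot returns 0). Adjacent segments of one image give
  the per-image tortuosity summary `mean θ`; matching segment indices across
  the two visits gives a per-patient direction-change profile.

* **Normalized mean slope.** The pointwise gradient
  `g_t = Δx / Δt` between consecutive centerline points, summarized as
  `Σ|g_t|` and the *normalized mean slope* `mean |g_t|`. A straight vertical
  stent scores 0; straightening lowers the score at follow-up.

Paired cohorts (each patient is their own control) are analyzed with a
Shapiro–Wilk normality check on the differences, a two-tailed paired t-test,
a Wilcoxon signed-rank test (exact null up to n = 25, mid-ranked ties, zeros
dropped), paired Cohen's `d = mean(diff)/sd(diff)`, and post hoc power from
the noncentral t distribution with noncentrality `d·√n`.

## Worked example

```bash
stentmorph phantom --n 3 --height 300 --width 96 --tube-radius 2 \
    --amplitude 14 --wavelength 220 --pigtail-radius 0 \
    --straightening 0.6 --between-sd 2 --seed 7 --out cohort/
stentmorph analyze --manifest cohort/manifest.csv --out metrics.csv
stentmorph cohort --metrics metrics.csv --out-prefix report
```

prints (tab-separated):

```
metric	n	pre	post	t_p	wilcoxon_p	|d|	power	flag
alg1_mean_angle_deg	3	10.11±0.245	13.02±1.69	0.07281	0.25	2.02	0.477
alg2_mean_abs	3	0.2652±0.0177	0.1568±0.0106	0.004315	0.25	8.76	1
alg2_abs_sum	3	71.33±4.75	42.17±2.84	0.004315	0.25	8.76	1
```

Three simulated patients straighten by 40% between visits (`--straightening
0.6`). The normalized mean slope (`alg2_mean_abs`) drops from 0.265 to 0.157
and the paired t-test flags the change (p = 0.004) even at n = 3, while the
mean consecutive segment angle (`alg1_mean_angle_deg`) moves the wrong way
and stays non-significant (p = 0.073): the slope metric tracks global
straightening, segment-angle averaging does not. (The exact Wilcoxon p
cannot fall below 0.25 at n = 3, and the absolute-sum variant duplicates the
mean here because all centerlines have equal length.) The full report,
including Shapiro–Wilk, effect sizes and power, is written to
`report.csv`/`report.json` with the run configuration embedded.

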