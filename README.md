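# gazeload

Content-independent eye-metric analysis of mental load for VR eye tracking.

When a listener strains to understand speech, their eyes give it away even
though the task is purely auditory: the pupil dilates and its variability
drops, fixations become fewer, voluntary glances at irrelevant content
decline, and the binocular focus drifts behind the surface being looked at
("staring through" it).  `gazeload` implements the full analysis chain for
detecting these signatures in head-mounted-display eye-tracking recordings
of a four-condition listening paradigm (native/foreign language × familiar/
unfamiliar style), together with a synthetic session generator that lets
every stage be validated against known ground truth — no proprietary
recordings required.

The package is aimed at researchers analyzing binocular HMD eye-tracking
logs (pupillometry, vergence, gaze events) and at anyone who needs a tested
reference implementation of this preprocessing-and-statistics chain.

## The metrics

For each trial (one participant listening to one audio condition), sampled
non-uniformly at ~90 Hz:

* **Pupil size** — blink runs (sentinel `-1` or out-of-range values) are
  extended 200 ms each way, merged, linearly interpolated, smoothed with a
  5-sample moving average per eye, combined binocularly, and
  baseline-corrected against the 0.5–2 s window.
* **Focus offset** — with H the head, S the gazed surface point and F the
  closest approach of the two gaze rays,

      offset = ((F − H)·u − |S − H|) / |S − H|,  u = (S − H)/|S − H|

  a dimensionless, scale-invariant vergence measure: positive when the eyes
  converge behind the surface.  Smoothed with a Savitzky–Golay filter
  (window 201, order 3) per contiguous valid segment and centered on each
  participant's median.
* **Fixations and saccades** — the combined gaze ray is projected onto a
  virtual screen 3 m ahead in head space (sized per trial from the
  0.0025-quantile-trimmed gaze cloud, 150 dpi) and classified by an
  adaptive velocity threshold (iterative mean + 3 SD clipping) on the real
  timestamps.
* **Section aggregates** — the first four 10-s sections per trial are the
  statistical unit (mean/variance/event counts), feeding a Shapiro–Wilk /
  Levene / Kruskal–Wallis chain with pairwise Wilcoxon rank-sum tests,
  Benjamini–Hochberg adjustment and pooled-SD Cohen's d, plus a per-poster
  distraction ratio for the content-dependent check.

See `docs/methods.md` for the full model description and defaults.

## Worked example

Simulate a small cohort with the default injected load effects (inverted-U
profile peaking at the third condition), run the pipeline, and look at the
pupil battery:

```python
import gazeload as gz

sessions = [s for s, _ in gz.simulate_cohort(gz.GeneratorConfig(), 11, seed=1)]
result = gz.run_pipeline(sessions)

g = result.aggregates.groupby("condition")["pupil_mean"].mean()
print(g.round(4).to_dict())
report = result.reports["pupil_mean"]
print(f"KW chi2({report.omnibus_df}) = {report.omnibus_stat:.2f}, p = {report.omnibus_p:.2e}")
for pw in report.pairwise:
    if "EN-Familiar" in pw.pair:
        print(pw.pair, f"adj p = {pw.p_adjusted:.3g}", f"d = {pw.cohens_d:.2f}")
```

prints (seed 1):

```
{'EN-Familiar': 0.1015, 'EN-Unfamiliar': 0.0022, 'JP-Familiar': -0.0411, 'JP-Unfamiliar': 0.0101}
KW chi2(3) = 27.41, p = 4.83e-06
('JP-Familiar', 'EN-Familiar') adj p = 4.78e-06 d = 1.20
('JP-Unfamiliar', 'EN-Familiar') adj p = 0.00171 d = 0.76
('EN-Familiar', 'EN-Unfamiliar') adj p = 0.000511 d = 0.87
```

The peak condition (`EN-Familiar`) shows the largest baseline-corrected
pupil mean (~0.11 mm above baseline — the injected peak shift of 0.118 mm
times the 0.91 onset-envelope weighting), the omnibus flags the metric, and
every pairwise contrast against the peak survives adjustment.  The same
`result` carries the focus-offset, fixation-count and distraction-ratio
tables.

A CLI wraps the same chain for shell use:

```bash
gazeload simulate --out sessions/ --participants 11 --seed 1
gazeload run --in sessions/ --out results/
gazeload info sessions/P01.csv
```

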