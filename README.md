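# kinemagree

Concurrent-validity analysis of clinically relevant motion parameters measured
by two 3D motion-capture systems — for example a marker-based optical system
(the clinical gold standard, ~120 Hz, millimetre-level noise) recorded
simultaneously with a markerless RGB-D method (~30 Hz, centimetre-level
noise, occasional tracking failures).

## Who this is for

Researchers in rehabilitation biomechanics and human motion analysis who need
to quantify how well a new tracking method agrees with an established
reference — not at the level of raw joint positions, but at the level of the
parameters clinicians actually use: maximum joint angles, reach distances,
jump height, centre-of-mass weight shift, movement speed and movement
smoothness.

Because paired clinical recordings are rarely shareable, the package includes
a first-class synthetic study generator: a parametric stick-figure skeleton
performs five movement tasks (reach across the midline, trunk bending,
standing straight leg raise, squats, jumping jacks) via piecewise
minimum-jerk choreography, and is then "observed" by both capture systems
with configurable sampling rate, Gaussian noise, frame dropout and limb-jump
artifacts. Every stage of the analysis pipeline is therefore testable end to
end, with known ground truth.

## The statistics at its core

For paired measurements \(a_i\) (test system) and \(b_i\) (reference), with
differences \(d_i = a_i - b_i\):

* **Time series** (angles, displacements, speeds over time): Pearson's
  \(r\) per participant on the common 30 Hz grid, averaged (mean, SD) across
  participants, plus the mean absolute difference.
* **Peaks and smoothness** (one number per recording): mean absolute error
  \(\mathrm{MAE} = \overline{|d|}\), and Bland–Altman analysis — bias
  \(\bar d\), limits of agreement \(\bar d \pm 1.96\,s_d\) (expected to
  contain ~95 % of differences under normality), and a paired t-test on the
  bias.
* **Smoothness**: the modified spectral arc length (SPARC) — the negative
  arc length of the normalized magnitude spectrum \(\hat V(\omega)\) of the
  movement speed profile up to an adaptive cutoff \(\omega_c\),
  \(-\int_0^{\omega_c}\sqrt{(1/\omega_c)^2 + (d\hat V/d\omega)^2}\,d\omega\).
  Values are ≤ 0; closer to zero means smoother. Rhythmic movements are
  scored per repetition and averaged.

All angle parameters are scalar three-point angles computed identically for
both systems from joint positions (e.g. the elbow angle from the shoulder,
elbow and wrist joints), so between-system differences reflect tracking
accuracy, not angle conventions. No smoothing or filtering is applied
anywhere; frames in which a system did not detect the body are excluded
pairwise, never interpolated.

## Worked example

Run the virtual study for two tasks (23 synthetic participants, 120 Hz
reference with 0.5 mm noise vs 30 Hz test stream with 7.3 mm per-axis noise,
rare dropouts and limb-jump artifacts):

```bash
kinemagree run --seed 1 --tasks reach,jumping_jacks --out out/
```

which prints (abridged):

```
         task      parameter  n   r_mean     r_sd   mae_mean units
jumping_jacks    ankle_speed 23 0.884942 0.086138 145.275535  mm/s
jumping_jacks    wrist_speed 23 0.993760 0.002146 127.979097  mm/s
        reach    elbow_angle 23 0.934641 0.031677   3.742451   deg
        reach trunk_rotation 23 0.975365 0.008448   2.081197   deg

         task          parameter  n       mae      bias  loa_lower  loa_upper       p_bias units
jumping_jacks        jump_height 23 13.796890 13.796890   8.505316  19.088464 1.831442e-17    mm
jumping_jacks              sparc 23  0.072909  0.072909   0.034278   0.111539 1.605816e-14     -
        reach max_reach_distance 23 16.152487 16.152487 -22.038209  54.343182 6.401080e-04    mm
        reach              sparc 17  0.364154 -0.038398  -0.871112   0.794316 7.143023e-01     -
```

Reading it: wrist speed during jumping jacks correlates near-perfectly
between the systems (r = 0.99) while ankle speed is lower (r = 0.88, the
fast-moving feet suffer more from noise at 30 Hz). Jump height shows a
+13.8 mm bias — the noisy test stream systematically inflates a
maximum-over-frames statistic — with limits of agreement of roughly 8 to
19 mm. The reach-task SPARC row keeps only 17 of 23 participants: recordings
whose smoothness window contained dropout frames are excluded and listed in
`out/exclusions.csv` rather than silently dropped. `out/` also contains the
two agreement tables, the tidy per-recording parameter values, the per-pair
retention log and the fully resolved configuration for reproducibility.

The same pipeline is available as a library (`kinemagree.run_study`,
`kinemagree.generate_study`, `kinemagree.bland_altman`, `kinemagree.sparc`,
…), and `kinemagree generate-study` / `extract-params` / `agree` expose the
individual stages.

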