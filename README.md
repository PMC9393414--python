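# somnocam

Non-contact sleep-stage estimation for young children (0–6 years) from
sleep video.  A fixed camera over the bed, sampling at 2 frames per
second, is enough to recover the coarse four-stage architecture of a
night — Wake, Light (N1+N2), Deep (N3) and REM — because the amount,
frequency and timing of body movement differ systematically between
stages: large and frequent in Wake, frequent in Light, sparser in REM,
nearly absent in Deep.

The package is aimed at researchers prototyping camera-based sleep
monitors for children, where contact sensors (and full polysomnography in
particular) are poorly tolerated and no public video datasets exist: every
stage of the pipeline can also be exercised on synthetic recordings with
controlled stage-movement structure.

## Method

1. **ROI rectification.**  The bedding area, outlined by four manually
   chosen corners, is warped to a rectangle by a projective
   ("trapezoidal") correction, excluding off-bed motion such as a parent
   entering the room.
2. **Dual-lag frame differencing.**  For each frame $I_n$, the difference
   image $|I_n - I_{n-\ell}|$ is binarized at a luminance threshold and
   the white pixels counted, at two lags: $\ell = 1$ frame (0.5 s, fast
   movements, `diff_fast`) and $\ell = 6$ frames (3.0 s, slow movements,
   `diff_slow`).
3. **Six parameters per 30 s epoch** (the clinical scoring interval; 60
   samples per epoch, windows indexed from the epoch start $n$):
   * `SumMean30` $= \frac{1}{60}\sum_{i=n}^{n+59}(d^{fast}_i + d^{slow}_i)$ — short-term movement magnitude;
   * `PropMean300` $= \log_{10}\frac{1}{600}\sum_{i=n}^{n+599} d^{fast}_i \cdot d^{slow}_i$, clamped to 0 when the mean product is below 1 — five-minute movement frequency;
   * `SumMean300` — the 600-sample moving average of $d^{fast}+d^{slow}$ — long-term magnitude;
   * `NonBM` — a stillness counter, reset whenever $d^{fast}_i+d^{slow}_i > k$, else incremented — duration of the stationary state;
   * `Epoch` $= (n+59)/60$ — elapsed time (Deep dominates early night, REM late);
   * `Variance30` — the population variance of $d^{fast}+d^{slow}$ within the epoch — short-term movement frequency.
4. **Per-recording standardization.**  Each parameter is z-scored within
   its night, removing body-size and sleep-duration differences between
   children.
5. **Classification.**  An extremely-randomized-trees ensemble (100
   trees) maps the six standardized parameters to the four stages, trained
   and evaluated separately for the 0–2 and 3–6 year age groups with
   leave-one-night-out cross-validation.  Reports give the 4×4 confusion
   matrix, per-stage accuracy/sensitivity/specificity, total accuracy and
   Cohen's kappa, plus an optional two-component PCA projection of the
   feature space.

## Worked example

Simulate a six-night infant cohort and evaluate it:

```sh
$ somnocam simulate --preset 0-2 --nights 6 --epochs 900 --seed 0 --out cohort
wrote 6 recordings (900 epochs each) to cohort
$ somnocam evaluate --cohort cohort/cohort.yaml --group 0-2 --seed 0 \
      --out report.json --pca-out pca.csv
PCA explained variance: 46.8%, 17.4% (cumulative 64.2%)
6 folds: total accuracy 75.5 +/- 4.5%, kappa 0.64 +/- 0.07
```

Each simulated night is a 900-epoch (7.5 h) hypnogram from a sticky
Markov chain with infant-like stage proportions, plus a stage-conditioned
movement series.  The evaluation holds out each night in turn: here the
classifier recovers 75.5% of epochs (4-class chance is 25%; a
chance-level classifier would give kappa 0) and two principal components
carry 64.2% of the feature variance.  `report.json` contains the per-fold
confusion matrices and per-stage metrics.

For real video, `somnocam extract --video night1.mp4 --roi roi.yaml
--out movements.csv` produces the movement CSV and `somnocam features`
the per-epoch parameters; `roi.yaml` lists the four bed corners.  The
same steps work on a directory of PNG frames, e.g. toy video rendered by
`somnocam.simulate.render_video`.

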