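# boldperf

Reperfusion BOLD-MRI tissue-perfusion analysis for the lower limb.

In peripheral arterial occlusive disease (PAOD) the crucial deficit —
skeletal-muscle perfusion — is not measured directly by any routine imaging
test. Blood-oxygenation-level-dependent (BOLD) MRI offers a contrast-free
window on it: deoxyhemoglobin is paramagnetic, so the effective transverse
relaxation time T2\* of muscle tracks the local oxy/deoxyhemoglobin ratio.
In a cuff-occlusion protocol a multi-echo gradient-echo series is acquired
continuously while the calf goes through rest (60 s), thigh-cuff ischemia
(300 s) and reperfusion (300 s) at 3.2 s temporal resolution, and the
reactive-hyperemia response of the gastrocnemius and soleus muscles is
quantified from ROI-mean T2\*-time curves.

`boldperf` implements that analysis as a tested, reusable pipeline, with a
synthetic phantom generator standing in for patient data:

- **synthetic phantoms / cohorts** — disk phantoms whose per-region T2\*
  follows a three-phase model (constant baseline BL; exponential decline
  during occlusion; gamma-variate hyperemic response
  `T2*(τ) = T2*_rel + (peak − T2*_rel)(τ/TTP)^α e^{α(1−τ/TTP)}` peaking at
  exactly `τ = TTP` with `peak = BL + overshoot`), plus two-group cohorts
  drawn at the published PAOD/control distributions of BL, overshoot, TTP
  and ankle-brachial index (ABI), with a latent-severity coupling that makes
  TTP rise as ABI falls;
- **dynamic T2\* mapping** — pixel-wise weighted least squares on
  `ln S_i = ln S₀ − TE_i·R2*` (variance-stabilizing signal-squared weights,
  one reweighting pass on the fitted signal), clamped to 1–200 ms;
- **motion correction & ROI curves** — integer-translation registration of
  first-echo frames by normalized cross-correlation, transforms propagated
  to the ROI masks, ROI-mean T2\* extracted over valid pixels;
- **curve features** — BL (mean over the 60 s rest phase), HPV (post-release
  maximum, optional moving-average smoothing), TTP (delay from cuff release
  to HPV) and overshoot (HPV − BL);
- **cohort statistics** — Mann-Whitney U (exact tie-aware permutation null
  for small samples, tie-corrected normal approximation otherwise) and
  Spearman rank correlation of TTP against ABI, with strength bands
  (0.10–0.39 weak, 0.40–0.69 moderate, 0.70–0.89 strong, ≥0.90 very strong).

## Worked example

Run the full synthetic pipeline (simulate → fit → register/extract →
features → analyze) for a small cohort:

```python
from dataclasses import replace
from boldperf import (CohortParams, PAOD_DEFAULTS, CONTROL_DEFAULTS,
                      RunConfig, run_pipeline)

cfg = RunConfig(seed=1, cohort=CohortParams(
    seed=1, paod=replace(PAOD_DEFAULTS, n=8),
    control=replace(CONTROL_DEFAULTS, n=6)))
report = run_pipeline(cfg, "demo_run")
print(report["correlations"].round(4).to_string(index=False))
```

which prints (seed 1):

```
    roi_label    feature  n     rho  p_two_sided   band
gastrocnemius ttp_vs_abi 14 -0.8901       0.0000 strong
       soleus ttp_vs_abi 14 -0.8462       0.0001 strong
```

i.e. within the simulated cohort, longer time-to-peak goes with lower
ankle-brachial index in both muscles. The comparisons table from the same
run shows the group separation in TTP (gastrocnemius 116.4 ± 46.1 s PAOD vs
46.9 ± 15.6 s control, Mann-Whitney p = 0.003) while baseline T2\* does not
differ (p = 0.28) — the qualitative pattern expected from the underlying
group distributions.

The same stages are available from the shell:

```sh
boldperf simulate --config cohort.yaml --out data/ --seed 1
boldperf fit      --in data/paod-01.nii.gz --sidecar data/paod-01.json --out t2map.nii.gz
boldperf extract  --t2map t2map.nii.gz --roi roi.nii.gz --sidecar data/paod-01.json \
                  --series data/paod-01.nii.gz --out curve.tsv
boldperf features --curve curve.tsv --sidecar data/paod-01.json --window 3 --out features.tsv
boldperf analyze  --features features.tsv --manifest data/cohort.tsv --out report/
boldperf run      --config run.yaml --out run1/ --seed 1
```

For a noiseless control-like phantom (BL 24.6 ms, overshoot 1.49 ms,
TTP 48 s) `boldperf features` prints

```
BL=24.60 ms  HPV=26.09 ms  TTP=48.0 s  overshoot=1.49 ms
```

recovering the generating parameters exactly.

Series are 4D NIfTI-1 `(row, col, echo, frame)` with a JSON sidecar
(`echo_times_ms`, `frame_times_s`, schedule, ground truth); masks are 8-bit
NIfTI-1 label images; curves, features and statistics are TSV.

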