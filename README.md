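# eegsel

Subband EEG features and NSGA-II channel/feature selection for two-class
resting-state EEG studies (mild cognitive impairment vs healthy controls).

Classifying MCI from scalp EEG typically starts from a full clinical montage
(19 channels, 10–20 system) and hundreds of subband features, most of which
are redundant or noise. `eegsel` implements the complete wrapper-selection
pipeline for this problem:

1. **Preprocessing** — 0.5–64 Hz zero-phase band-pass, common-average
   re-reference, non-overlapping 10-s segmentation (ch × N segments).
2. **Subband decomposition** — variational mode decomposition (5 VMFs +
   residual + original → 7 sub-signals per channel) or a 5-level DWT
   (A5, D2–D5 + original → 6 sub-signals; at 256 Hz the dyadic bands line up
   with 0–4, 4–8, 8–16, 16–32, 32–64 Hz).
3. **Features** — one scalar measure per sub-signal, chosen from STD, IQR,
   log band power, Teager energy, Shannon / histogram / sure / threshold
   entropy, and Katz's / Higuchi's fractal dimensions; a 19-channel montage
   yields 7 × 19 = 133 (VMD) or 6 × 19 = 114 (DWT) features per segment.
4. **Evaluation** — leave-one-subject-out cross-validation (one fold per
   subject; CA = mean per-fold N_correct/N_total × 100 %) of bagged-tree RF,
   least-squares SVM, linear/quadratic DA and KNN with ten distance options.
5. **Selection** — NSGA-II over binary channel masks (21-gene chromosome for
   19 channels + KNN's two hyperparameter genes) or per-column feature masks,
   jointly with the classifier hyperparameters:

   minimize No_ch (or No_feat), maximize averag CA, subject to No_ch ≥ 1 —
   returning the Pareto front of subset size vs LOSO accuracy.

A synthetic cohort generator plants channel-localized band-power contrasts
(with subject-level gain and spectral-profile confounds), so every stage —
including recovery of the planted channels by the optimizer — is testable
without any external recordings. Real data can be supplied as EDF files or
delimited matrices plus a `subject_id,label,path` manifest.

## Worked example

```bash
python examples/04_channel_selection.py
```

builds a 24-subject synthetic cohort in which the MCI-like class has theta
(4–8 Hz) power raised ×4 on T5 and lowered ×4 on O1, extracts DWT
Teager-energy features, and runs channel-mode NSGA-II (population 32,
30 generations, KNN). It prints:

```
all-channel LOSO CA: 79.9%

Pareto front (size vs LOSO CA):
 size    CA classifier                  params selected
    1 92.36        KNN    k=1, distance=cosine     [T5]
    2 95.14        KNN k=5, distance=chebychev [T5, O1]

planted pair (T5, O1) recovered at size 2: True
best front solution: CA 95.1% with 2 channels (vs 79.9% using all 8)
```

Reading: one front row per non-dominated trade-off. Using all 8 channels,
KNN reaches 79.9 % subject-level accuracy; the optimizer finds that the two
planted channels alone reach 95.1 % (no single channel can, because each is
confounded by the subject's own theta level — only the T5-vs-O1 contrast
cancels it). Other examples cover cohort synthesis, decomposition, the
feature/LOSO pipeline and the 10-fold-vs-LOSO leakage contrast.

The same stages are available from a thin CLI (`eegsel synth`,
`eegsel features`, `eegsel evaluate`, `eegsel select-channels`,
`eegsel select-features`).

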