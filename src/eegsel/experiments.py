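"""Canonical study harnesses: reference cohorts and end-to-end experiments.

These wrap the library into the three study designs the toolkit is built
around, at sizes that run on a single CPU in minutes:

* ``recovery`` — a 24-subject cohort with a complementary planted theta
  contrast (theta power raised on T5, lowered on O1 for the MCI-like class)
  against per-subject global-gain and spectral-profile confounds shared
  across channels.  A single channel is then intrinsically confounded by the
  subject's own theta level, while the exact planted pair cancels it — so
  the two-channel solution is the Pareto-optimal target the channel-mode
  NSGA-II search should recover.
* ``leakage`` — a null cohort (no class effect) whose subjects differ only
  in amplitude gains; segment-level k-fold CV exploits within-subject
  similarity and scores far above leave-one-subject-out, quantifying the
  leakage that subject-unaware CV introduces.
* ``chance`` — label permutation on a null cohort, the sanity floor.

An 8-channel montage and 60-s recordings keep run times small; the
contrasts these harnesses demonstrate do not depend on the full 19-channel,
10-minute layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import ClassifierSpec, kfold_evaluate, loso_evaluate
from .features import FeatureMatrix, MeasureSpec, build_feature_matrix
from .preprocess import preprocess_recordings
from .select import ParetoFront, make_encoding, nsga2_run
from .synth import CohortSpec, EffectSpec, generate_cohort

RECOVERY_MONTAGE = ("Fp1", "F3", "Cz", "P3", "T5", "O1", "O2", "F4")
PLANTED_PAIR = ("T5", "O1")


def recovery_cohort_spec(seed: int = 0, duration_s: float = 60.0) -> CohortSpec:
    """24-subject cohort with the complementary planted theta contrast."""
    effects = (
        EffectSpec(informative_channels=("T5",), band=(4.0, 8.0), power_ratio=4.0),
        EffectSpec(informative_channels=("O1",), band=(4.0, 8.0), power_ratio=0.25),
    )
    return CohortSpec(n_class1=11, n_class0=13, duration_s=duration_s, fs=256.0,
                      montage=RECOVERY_MONTAGE, effect=effects, seed=seed,
                      subject_gain_sd=0.3, channel_gain_sd=0.05,
                      band_profile_sd=0.35)


def recovery_feature_matrix(seed: int = 0, duration_s: float = 60.0) -> FeatureMatrix:
    recs = generate_cohort(recovery_cohort_spec(seed, duration_s))
    segs = preprocess_recordings(recs)
    return build_feature_matrix(segs, "dwt", spec=MeasureSpec("TeEng"))


@dataclass(frozen=True)
class RecoveryRun:
    front: ParetoFront
    pair_recovered: bool      # front holds a size-2 solution == planted pair
    best_ca: float
    best_size: int


def run_channel_recovery(fm: FeatureMatrix, seed: int, pop_size: int = 32,
                         max_iter: int = 30) -> RecoveryRun:
    """One channel-mode NSGA-II run; checks the planted pair is on the front."""
    enc = make_encoding(fm, "channel", "KNN")
    front = nsga2_run(fm, enc, pop_size=pop_size, max_iter=max_iter, seed=seed)
    pair = set(PLANTED_PAIR)
    recovered = any(s.objectives.size == 2 and set(s.selected_names) == pair
                    for s in front.solutions)
    best = front.best()
    return RecoveryRun(front=front, pair_recovered=recovered,
                       best_ca=best.objectives.quality,
                       best_size=best.objectives.size)


def leakage_cohort_spec(seed: int = 0) -> CohortSpec:
    """Null cohort (no class effect) with subject-specific amplitude offsets."""
    effect = EffectSpec(informative_channels=(), band=(4.0, 8.0), power_ratio=1.0)
    return CohortSpec(n_class1=6, n_class0=6, duration_s=60.0, fs=256.0,
                      montage=RECOVERY_MONTAGE[:6], effect=effect, seed=seed,
                      subject_gain_sd=0.4, channel_gain_sd=0.05,
                      band_profile_sd=0.25)


def leakage_demo(seed: int = 0,
                 clf: "ClassifierSpec | None" = None) -> "tuple[float, float]":
    """(tenfold CA, LOSO CA) on the subject-offset null cohort.

    Segment-level 10-fold CV can match test segments to same-subject training
    segments via the subject's amplitude signature, so it scores far above
    LOSO, which by construction cannot.
    """
    clf = clf if clf is not None else ClassifierSpec("KNN", {"k": 1})
    recs = generate_cohort(leakage_cohort_spec(seed))
    segs = preprocess_recordings(recs)
    fm = build_feature_matrix(segs, "dwt", spec=MeasureSpec("STD"))
    tenfold = kfold_evaluate(fm, None, clf, n_splits=10, seed=seed).CA
    loso = loso_evaluate(fm, None, clf, seed=seed).CA
    return tenfold, loso


def permuted_labels(fm: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Feature matrix with labels permuted at the SUBJECT level (seeded)."""
    rng = np.random.default_rng(seed)
    subjects = list(dict.fromkeys(fm.subject_ids))
    orig = {s: l for s, l in zip(fm.subject_ids, fm.labels)}
    perm = rng.permutation([orig[s] for s in subjects])
    new_lab = {s: int(l) for s, l in zip(subjects, perm)}
    return FeatureMatrix(values=fm.values, columns=fm.columns,
                         subject_ids=fm.subject_ids,
                         labels=tuple(new_lab[s] for s in fm.subject_ids),
                         measure=fm.measure, method=fm.method)
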