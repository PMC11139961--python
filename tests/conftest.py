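"""Shared fixtures: small synthetic cohorts and feature matrices.

Everything is generated programmatically and seeded; session scope keeps the
expensive cohorts to one build per run.
"""

import numpy as np
import pytest

import eegsel as es

SMALL_MONTAGE = ("Fp1", "F3", "Cz", "P3", "T5", "O1")


@pytest.fixture(scope="session")
def small_cohort_spec():
    """6-channel, 30-s, 4+4-subject cohort with a strong theta effect on Cz."""
    return es.CohortSpec(
        n_class1=4, n_class0=4, duration_s=30.0, fs=256.0,
        montage=SMALL_MONTAGE,
        effect=es.EffectSpec(informative_channels=("Cz",), band=(4.0, 8.0),
                             power_ratio=4.0),
        seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    return es.generate_cohort(small_cohort_spec)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    return es.preprocess_recordings(small_cohort)


@pytest.fixture(scope="session")
def small_fm(small_segments):
    """DWT Teager-energy feature matrix of the small cohort (24 rows x 36 cols)."""
    return es.build_feature_matrix(small_segments, "dwt",
                                   spec=es.MeasureSpec("TeEng"))


@pytest.fixture(scope="session")
def separable_fm():
    """A trivially separable feature matrix: opposite ramp profiles per class.

    8 subjects x 5 segments, 4 features; class-0 rows follow a descending
    ramp (20, 15, 10, 5), class-1 an ascending one, with noise sd 0.1.  The
    classes separate in location AND in row shape, so both metric distances
    and the scale/shift-invariant ones (correlation, spearman, cosine)
    resolve them — even after per-fold column standardization.
    """
    rng = np.random.default_rng(5)
    ramp = np.array([5.0, 10.0, 15.0, 20.0])
    rows, sids, labels = [], [], []
    for s in range(8):
        label = s % 2
        for _ in range(5):
            profile = ramp if label else ramp[::-1]
            rows.append(profile + rng.normal(0.0, 0.1, 4))
            sids.append(f"s{s}")
            labels.append(label)
    columns = tuple((f"ch{i}", "Orig") for i in range(4))
    return es.FeatureMatrix(values=np.array(rows), columns=columns,
                            subject_ids=tuple(sids), labels=tuple(labels),
                            measure=es.MeasureSpec("STD"), method="dwt")
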