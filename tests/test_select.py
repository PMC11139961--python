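"""NSGA-II machinery: decoding, sorting, crowding, and whole-loop behaviour."""

import itertools

import numpy as np
import pytest

import eegsel as es
from eegsel.select import (FitnessCache, Objectives, VariationParams, dominates,
                           report_front, selection_counts)


def brute_force_fronts(objs):
    """O(n^2) dominance-matrix front assignment (independent of the fast sort)."""
    remaining = set(range(len(objs)))
    fronts = []
    while remaining:
        front = [i for i in remaining
                 if not any(dominates(objs[j], objs[i])
                            for j in remaining if j != i)]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


def brute_force_pareto(objs):
    """Non-dominated (size, quality) pairs of a finite objective set."""
    return {(o.size, round(o.quality, 9)) for o in objs
            if not any(dominates(p, o) for p in objs)}


@pytest.fixture(scope="module")
def tiny_fm():
    """6-channel cohort small enough to enumerate every channel subset."""
    spec = es.CohortSpec(
        n_class1=4, n_class0=4, duration_s=30.0, fs=128.0,
        montage=("Fp1", "F3", "Cz", "P3", "T5", "O1"),
        effect=es.EffectSpec(informative_channels=("Cz", "O1"),
                             band=(4.0, 8.0), power_ratio=5.0),
        seed=17, subject_gain_sd=0.2, channel_gain_sd=0.1,
        band_profile_sd=0.1)
    recs = es.generate_cohort(spec)
    segs = es.preprocess_recordings(recs, high_hz=32.0)
    return es.build_feature_matrix(segs, "dwt", es.DWTParams(levels=4),
                                   es.MeasureSpec("TeEng"))


class TestDecode:
    def test_channel_mode_expands_to_all_band_columns(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        assert enc.n_genes == len(small_fm.channel_names) + 2
        chrom = es.Chromosome((1,) * enc.n_mask_genes, (3, 1))
        mask, spec = es.decode(chrom, enc)
        assert mask.all() and mask.size == small_fm.n_features
        assert spec.family == "KNN"
        assert spec.params == {"k": 3, "distance": "euclidean"}

    def test_single_channel_selects_its_six_columns(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        genes = [0] * enc.n_mask_genes
        genes[enc.mask_names.index("Cz")] = 1
        mask, _ = es.decode(es.Chromosome(tuple(genes), (5, 2)), enc)
        assert mask.sum() == 6
        assert all(ch == "Cz" for (ch, _), m in zip(small_fm.columns, mask) if m)

    def test_feature_mode_mask_is_verbatim(self, small_fm):
        enc = es.make_encoding(small_fm, "feature", "SVM")
        genes = [0] * enc.n_mask_genes
        genes[7] = 1
        mask, spec = es.decode(es.Chromosome(tuple(genes), (2,)), enc)
        assert mask.sum() == 1 and mask[7]
        assert spec.params["kernel"] == "polynomial"

    def test_distance_index_table(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        for idx, name in enumerate(es.KNN_DISTANCES, start=1):
            _, spec = es.decode(
                es.Chromosome((1,) * enc.n_mask_genes, (1, idx)), enc)
            assert spec.params["distance"] == name

    def test_out_of_domain_param_rejected(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        with pytest.raises(ValueError):
            es.decode(es.Chromosome((1,) * enc.n_mask_genes, (11, 1)), enc)

    def test_channel_chromosome_length_for_19_channels(self):
        # 19 mask genes + 2 KNN parameter genes = 21
        rng = np.random.default_rng(0)
        segs = es.SegmentSet(segments=(rng.normal(size=(19, 128)),) * 2,
                             subject_ids=("a", "b"), labels=(0, 1), fs=64.0,
                             montage=es.STANDARD_1020, seg_len_s=2.0)
        fm = es.build_feature_matrix(segs, "dwt", es.DWTParams(levels=4),
                                     es.MeasureSpec("STD"))
        enc = es.make_encoding(fm, "channel", "KNN")
        assert enc.n_genes == 21


class TestNondominatedSort:
    def test_tradeoff_pair_shares_front(self):
        # incomparable: fewer channels but lower accuracy vs more-but-better
        fronts = es.fast_nondominated_sort([Objectives(2, 85), Objectives(3, 90)])
        assert fronts == [[0, 1]]

    def test_dominated_points_demoted(self):
        # (2,90) beats everything; (2,88) beats (3,88) (same quality, smaller)
        objs = [Objectives(2, 90), Objectives(3, 88), Objectives(2, 88)]
        fronts = es.fast_nondominated_sort(objs)
        assert fronts == [[0], [2], [1]]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(200 + trial)
        objs = [Objectives(int(rng.integers(1, 8)), float(rng.integers(50, 101)))
                for _ in range(int(rng.integers(5, 50)))]
        fast = [sorted(f) for f in es.fast_nondominated_sort(objs)]
        assert fast == brute_force_fronts(objs)


class TestCrowdingDistance:
    def test_front_of_two_all_infinite(self):
        d = es.crowding_distance([Objectives(1, 90), Objectives(3, 95)])
        assert np.isinf(d).all()

    def test_equally_spaced_interior_distance_is_two(self):
        d = es.crowding_distance([Objectives(1, 80), Objectives(2, 90),
                                  Objectives(3, 100)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_degenerate_identical_front(self):
        d = es.crowding_distance([Objectives(2, 90)] * 4)
        assert np.isfinite(d).sum() >= 2  # interior entries, guarded division
        assert all(v == 0.0 for v in d[np.isfinite(d)])


class TestEvaluateIndividual:
    def test_all_ones_matches_full_evaluation(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        cache = FitnessCache(small_fm, enc, seed=0)
        chrom = es.Chromosome((1,) * enc.n_mask_genes, (3, 1))
        obj = es.evaluate_individual(chrom, enc, small_fm, cache=cache)
        direct = es.loso_evaluate(small_fm, None,
                                  es.ClassifierSpec("KNN", {"k": 3}), seed=0)
        assert obj.size == enc.n_mask_genes
        assert obj.quality == pytest.approx(direct.CA)

    def test_memoization(self, small_fm):
        enc = es.make_encoding(small_fm, "channel", "KNN")
        cache = FitnessCache(small_fm, enc, seed=0)
        chrom = es.Chromosome((1,) * enc.n_mask_genes, (3, 1))
        cache(chrom)
        cache(chrom)
        assert cache.n_calls == 2 and cache.n_unique == 1


class TestNSGA2Loop:
    def test_recovers_exhaustive_pareto_front(self, tiny_fm):
        """Pop-32 NSGA-II equals brute-force enumeration on a 6-channel problem."""
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        cache = FitnessCache(tiny_fm, enc, seed=0)
        all_objs = []
        for bits in itertools.product((0, 1), repeat=6):
            if sum(bits) == 0:
                continue
            for p in (1, 2):
                all_objs.append(cache(es.Chromosome(bits, (p,))))
        truth = brute_force_pareto(all_objs)
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            front = es.nsga2_run(tiny_fm, enc, pop_size=32, max_iter=30,
                                 seed=seed, fitness=cache)
            got = {(s.objectives.size, round(s.objectives.quality, 9))
                   for s in front.solutions}
            hits += got == truth
        assert hits >= 0.95 * n_runs

    def test_seeded_dominating_solution_survives(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        cache = FitnessCache(tiny_fm, enc, seed=0)
        # find the best single-channel genome by direct evaluation
        best = max((es.Chromosome(tuple(int(i == j) for i in range(6)), (p,))
                    for j in range(6) for p in (1, 2)),
                   key=lambda c: cache(c).quality)
        front = es.nsga2_run(tiny_fm, enc, pop_size=8, max_iter=10, seed=1,
                             fitness=cache, initial_population=[best])
        keys = {(s.chromosome.mask_genes, s.chromosome.param_genes)
                for s in front.solutions}
        assert (best.mask_genes, best.param_genes) in keys

    def test_budget_and_elitism_invariants(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        front = es.nsga2_run(tiny_fm, enc, pop_size=16, max_iter=8, seed=2)
        assert front.n_unique_evaluations <= 16 * 9
        best_per_gen = [max(o.quality for o in snap)
                        for snap in front.generation_log]
        assert all(b >= a - 1e-9 for a, b in zip(best_per_gen, best_per_gen[1:]))

    def test_front_internally_nondominated(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        front = es.nsga2_run(tiny_fm, enc, pop_size=16, max_iter=5, seed=3)
        for a in front.solutions:
            for b in front.solutions:
                assert a is b or not dominates(a.objectives, b.objectives)

    def test_seed_determinism(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        a = es.nsga2_run(tiny_fm, enc, pop_size=8, max_iter=5, seed=7)
        b = es.nsga2_run(tiny_fm, enc, pop_size=8, max_iter=5, seed=7)
        assert [(s.chromosome.mask_genes, s.chromosome.param_genes)
                for s in a.solutions] == \
               [(s.chromosome.mask_genes, s.chromosome.param_genes)
                for s in b.solutions]

    def test_invalid_run_parameters_rejected(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "DA")
        with pytest.raises(ValueError):
            es.nsga2_run(tiny_fm, enc, pop_size=3, max_iter=5)
        with pytest.raises(ValueError):
            es.nsga2_run(tiny_fm, enc, pop_size=8, max_iter=0)


class TestReporting:
    def test_report_rows_and_counts(self, tiny_fm):
        enc = es.make_encoding(tiny_fm, "channel", "KNN")
        front = es.nsga2_run(tiny_fm, enc, pop_size=8, max_iter=3, seed=0)
        rows = report_front(front)
        assert len(rows) == len(front.solutions)
        assert set(rows.columns) == {"size", "CA", "classifier", "params", "selected"}
        counts = selection_counts(front)
        assert counts["count"].sum() == sum(s.objectives.size
                                            for s in front.solutions)
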