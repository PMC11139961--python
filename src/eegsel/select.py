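"""NSGA-II selection of EEG channels or features jointly with classifier settings.

Two wrapper-selection problems share one machinery:

* channel mode — one binary gene per montage channel; a selected channel
  contributes ALL of its subband feature columns.  Objectives: minimize the
  number of selected channels (No_ch), maximize LOSO classification
  accuracy.  Constraint No_ch >= 1 enforced by repair.
* feature mode — one binary gene per (channel, band) feature column;
  objectives: minimize the number of selected features (No_feat), maximize
  LOSO accuracy.

Classifier hyperparameters ride along on the same chromosome as integer
genes (KNN: k 1..10 and distance index 1..10; SVM: kernel index 1..3; DA:
discriminant index 1..2; RF: tree depth 1..35), so subset and settings are
co-optimized.  A 19-channel KNN channel-selection chromosome therefore has
21 genes.

The optimizer is the standard elitist NSGA-II loop: fast non-dominated
sorting, crowding-distance diversity, binary tournament on (rank, crowding),
uniform crossover on mask genes, bit-flip mask mutation, single-point
exchange plus random-reset mutation on parameter genes, and (mu + lambda)
environmental selection.  Fitness (the LOSO accuracy) is memoized on the
decoded (mask, params) key, so duplicate genomes cost nothing and fitness is
a pure function within a run; the quality objective is internally minimized
as 100 - CA.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (ClassifierSpec, DA_TYPES, KNN_DISTANCES, KNN_MAX_K,
                       RF_MAX_DEPTH, SVM_KERNELS, loso_evaluate)
from .features import FeatureMatrix

_PARAM_DOMAINS: dict[str, tuple[tuple[int, int], ...]] = {
    "KNN": ((1, KNN_MAX_K), (1, len(KNN_DISTANCES))),
    "SVM": ((1, len(SVM_KERNELS)),),
    "DA": ((1, len(DA_TYPES)),),
    "RF": ((1, RF_MAX_DEPTH),),
}


@dataclass(frozen=True)
class ProblemEncoding:
    """Chromosome layout for one selection problem.

    ``mask_names`` gives the entity behind each mask gene: channel names in
    channel mode, ``CH|BAND`` column labels in feature mode.
    """

    mode: str  # 'channel' | 'feature'
    family: str
    mask_names: "tuple[str, ...]"
    columns: "tuple[tuple[str, str], ...]"  # feature-matrix column metadata

    def __post_init__(self) -> None:
        if self.mode not in ("channel", "feature"):
            raise ValueError("mode must be 'channel' or 'feature'")
        if self.family not in _PARAM_DOMAINS:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def n_mask_genes(self) -> int:
        return len(self.mask_names)

    @property
    def param_domains(self) -> "tuple[tuple[int, int], ...]":
        return _PARAM_DOMAINS[self.family]

    @property
    def n_genes(self) -> int:
        return self.n_mask_genes + len(self.param_domains)


def make_encoding(fm: FeatureMatrix, mode: str, family: str) -> ProblemEncoding:
    family = family.upper()
    if mode == "channel":
        names = fm.channel_names
    else:
        names = tuple(f"{ch}|{band}" for ch, band in fm.columns)
    return ProblemEncoding(mode=mode, family=family, mask_names=names,
                           columns=fm.columns)


@dataclass(frozen=True)
class Chromosome:
    mask_genes: "tuple[int, ...]"   # binary
    param_genes: "tuple[int, ...]"  # integers within encoding domains

    def __post_init__(self) -> None:
        if any(g not in (0, 1) for g in self.mask_genes):
            raise ValueError("mask genes must be binary")


@dataclass(frozen=True)
class Objectives:
    """size = No_ch or No_feat (minimized); quality = LOSO CA in % (maximized)."""

    size: int
    quality: float


def dominates(a: Objectives, b: Objectives) -> bool:
    """a dominates b: no worse on both objectives and strictly better on one."""
    return (a.size <= b.size and a.quality >= b.quality
            and (a.size < b.size or a.quality > b.quality))


@dataclass(frozen=True)
class Solution:
    chromosome: Chromosome
    objectives: Objectives
    selected_names: "tuple[str, ...]"
    classifier: ClassifierSpec


@dataclass(frozen=True)
class ParetoFront:
    solutions: "tuple[Solution, ...]"
    generation_log: "tuple[tuple[Objectives, ...], ...]"
    n_unique_evaluations: int
    n_fitness_calls: int

    def best(self) -> Solution:
        """Headline solution: maximum CA, ties broken by smaller subset."""
        return min(self.solutions,
                   key=lambda s: (-s.objectives.quality, s.objectives.size))


def decode(chrom: Chromosome, enc: ProblemEncoding) -> "tuple[np.ndarray, ClassifierSpec]":
    """Chromosome -> (boolean feature-column mask, ClassifierSpec)."""
    if len(chrom.mask_genes) != enc.n_mask_genes:
        raise ValueError("chromosome mask length does not match encoding")
    if len(chrom.param_genes) != len(enc.param_domains):
        raise ValueError("chromosome param length does not match encoding")
    for g, (lo, hi) in zip(chrom.param_genes, enc.param_domains):
        if not lo <= g <= hi:
            raise ValueError(f"param gene {g} outside domain [{lo}, {hi}]")
    mask = np.asarray(chrom.mask_genes, bool)
    if enc.mode == "channel":
        chosen = {name for name, g in zip(enc.mask_names, chrom.mask_genes) if g}
        column_mask = np.array([ch in chosen for ch, _ in enc.columns], bool)
    else:
        column_mask = mask.copy()

    fam = enc.family
    if fam == "KNN":
        spec = ClassifierSpec("KNN", {"k": int(chrom.param_genes[0]),
                                      "distance": KNN_DISTANCES[chrom.param_genes[1] - 1]})
    elif fam == "SVM":
        spec = ClassifierSpec("SVM", {"kernel": SVM_KERNELS[chrom.param_genes[0] - 1]})
    elif fam == "DA":
        spec = ClassifierSpec("DA", {"discriminant": DA_TYPES[chrom.param_genes[0] - 1]})
    else:
        spec = ClassifierSpec("RF", {"tree_depth": int(chrom.param_genes[0])})
    return column_mask, spec


class FitnessCache:
    """Memoized LOSO fitness keyed on the decoded (mask, params)."""

    def __init__(self, fm: FeatureMatrix, enc: ProblemEncoding, seed: int):
        self.fm = fm
        self.enc = enc
        self.seed = seed
        self._cache: dict = {}
        self.n_calls = 0

    @property
    def n_unique(self) -> int:
        return len(self._cache)

    def __call__(self, chrom: Chromosome) -> Objectives:
        self.n_calls += 1
        key = (chrom.mask_genes, chrom.param_genes)
        if key not in self._cache:
            column_mask, spec = decode(chrom, self.enc)
            if not column_mask.any():
                raise ValueError("decoded mask selects no columns (repair missing?)")
            ca = loso_evaluate(self.fm, column_mask, spec, seed=self.seed).CA
            self._cache[key] = Objectives(size=int(sum(chrom.mask_genes)),
                                          quality=float(ca))
        return self._cache[key]


def evaluate_individual(chrom: Chromosome, enc: ProblemEncoding,
                        fm: FeatureMatrix, seed: int = 0,
                        cache: "FitnessCache | None" = None) -> Objectives:
    """One chromosome's objectives; `cache` (a FitnessCache) memoizes."""
    if cache is None:
        cache = FitnessCache(fm, enc, seed)
    return cache(chrom)


def fast_nondominated_sort(objs: "list[Objectives]") -> "list[list[int]]":
    """Partition indices into fronts; front 0 is the non-dominated set."""
    n = len(objs)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    fronts = [[i for i in range(n) if domination_count[i] == 0]]
    while True:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        if not nxt:
            break
        fronts.append(sorted(nxt))
    return fronts


def crowding_distance(front_objs: "list[Objectives]") -> np.ndarray:
    """NSGA-II crowding distance; boundary solutions get +inf."""
    n = len(front_objs)
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    for values in (np.array([o.size for o in front_objs], float),
                   np.array([o.quality for o in front_objs], float)):
        order = np.argsort(values, kind="stable")
        vmin, vmax = values[order[0]], values[order[-1]]
        dist[order[0]] = dist[order[-1]] = np.inf
        if vmax > vmin:
            for pos in range(1, n - 1):
                i = order[pos]
                dist[i] += (values[order[pos + 1]] - values[order[pos - 1]]) / (vmax - vmin)
    return dist


@dataclass(frozen=True)
class VariationParams:
    """Genetic-operator settings (standard mixed binary/integer NSGA-II)."""

    crossover_rate: float = 0.9          # per-pair uniform crossover on mask genes
    mask_mutation_rate: "float | None" = None  # per-gene bit flip; default 1/n_mask
    param_mutation_rate: float = 0.1     # per-gene random reset
    init_density: float = 0.5            # P(mask gene = 1) in the initial population


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(len(mask))] = 1
    return mask


def _random_chromosome(enc: ProblemEncoding, rng: np.random.Generator,
                       density: float) -> Chromosome:
    mask = _repair((rng.random(enc.n_mask_genes) < density).astype(int), rng)
    params = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in enc.param_domains)
    return Chromosome(tuple(int(g) for g in mask), params)


def _tournament(rng, ranks, crowd):
    i, j = rng.integers(len(ranks)), rng.integers(len(ranks))
    if ranks[i] != ranks[j]:
        return i if ranks[i] < ranks[j] else j
    if crowd[i] != crowd[j]:
        return i if crowd[i] > crowd[j] else j
    return i


def _vary(p1: Chromosome, p2: Chromosome, enc: ProblemEncoding,
          vp: VariationParams, rng: np.random.Generator) -> "tuple[Chromosome, Chromosome]":
    m1 = np.array(p1.mask_genes)
    m2 = np.array(p2.mask_genes)
    g1 = list(p1.param_genes)
    g2 = list(p2.param_genes)
    if rng.random() < vp.crossover_rate:
        swap = rng.random(enc.n_mask_genes) < 0.5
        m1[swap], m2[swap] = m2[swap], m1[swap].copy()
        if len(g1) > 1:  # single-point exchange on param genes
            cut = int(rng.integers(1, len(g1)))
            g1[cut:], g2[cut:] = g2[cut:], g1[cut:]
        elif len(g1) == 1 and rng.random() < 0.5:
            g1[0], g2[0] = g2[0], g1[0]
    mut_rate = (vp.mask_mutation_rate if vp.mask_mutation_rate is not None
                else 1.0 / enc.n_mask_genes)
    for m in (m1, m2):
        flip = rng.random(enc.n_mask_genes) < mut_rate
        m[flip] = 1 - m[flip]
    for g in (g1, g2):
        for idx, (lo, hi) in enumerate(enc.param_domains):
            if rng.random() < vp.param_mutation_rate:
                g[idx] = int(rng.integers(lo, hi + 1))
    m1 = _repair(m1, rng)
    m2 = _repair(m2, rng)
    return (Chromosome(tuple(int(v) for v in m1), tuple(g1)),
            Chromosome(tuple(int(v) for v in m2), tuple(g2)))


def _solution(chrom: Chromosome, obj: Objectives, enc: ProblemEncoding) -> Solution:
    column_mask, spec = decode(chrom, enc)
    names = tuple(name for name, g in zip(enc.mask_names, chrom.mask_genes) if g)
    return Solution(chromosome=chrom, objectives=obj,
                    selected_names=names, classifier=spec)


def nsga2_run(fm: FeatureMatrix, enc: ProblemEncoding, pop_size: int = 32,
              max_iter: int = 30, op_params: VariationParams = VariationParams(),
              seed: int = 0,
              fitness: "FitnessCache | None" = None,
              initial_population: "list[Chromosome] | None" = None) -> ParetoFront:
    """Run the NSGA-II generational loop; returns the final non-dominated front.

    ``pop_size`` individuals evolve for ``max_iter`` generations; unique
    fitness evaluations are bounded by pop_size * (max_iter + 1).  The run is
    deterministic for a fixed seed (the LOSO inner seed is fixed to the same
    value, so fitness is a pure function of the genome).
    """
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be an even number >= 4")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if enc.n_mask_genes < 1:
        raise ValueError("encoding has no mask genes")
    rng = np.random.default_rng(seed)
    cache = fitness if fitness is not None else FitnessCache(fm, enc, seed)

    seeded = list(initial_population or [])[:pop_size]
    pop = seeded + [_random_chromosome(enc, rng, op_params.init_density)
                    for _ in range(pop_size - len(seeded))]
    objs = [cache(c) for c in pop]
    log: list[tuple[Objectives, ...]] = []

    for _ in range(max_iter):
        fronts = fast_nondominated_sort(objs)
        ranks = np.empty(len(pop), int)
        crowd = np.empty(len(pop))
        for r, front in enumerate(fronts):
            ranks[front] = r
            crowd[front] = crowding_distance([objs[i] for i in front])
        log.append(tuple(objs[i] for i in fronts[0]))

        offspring: list[Chromosome] = []
        while len(offspring) < pop_size:
            p1 = pop[_tournament(rng, ranks, crowd)]
            p2 = pop[_tournament(rng, ranks, crowd)]
            c1, c2 = _vary(p1, p2, enc, op_params, rng)
            offspring.extend([c1, c2])
        offspring = offspring[:pop_size]
        off_objs = [cache(c) for c in offspring]

        # (mu + lambda) elitist environmental selection
        comb = pop + offspring
        comb_objs = objs + off_objs
        fronts = fast_nondominated_sort(comb_objs)
        new_pop: list[Chromosome] = []
        new_objs: list[Objectives] = []
        for front in fronts:
            if len(new_pop) + len(front) <= pop_size:
                new_pop.extend(comb[i] for i in front)
                new_objs.extend(comb_objs[i] for i in front)
            else:
                cd = crowding_distance([comb_objs[i] for i in front])
                order = sorted(range(len(front)), key=lambda t: -cd[t])
                for t in order[: pop_size - len(new_pop)]:
                    new_pop.append(comb[front[t]])
                    new_objs.append(comb_objs[front[t]])
                break
        pop, objs = new_pop, new_objs

    fronts = fast_nondominated_sort(objs)
    log.append(tuple(objs[i] for i in fronts[0]))
    # deduplicate genomes in the returned front
    seen: dict = {}
    for i in fronts[0]:
        key = (pop[i].mask_genes, pop[i].param_genes)
        seen.setdefault(key, _solution(pop[i], objs[i], enc))
    solutions = tuple(sorted(seen.values(),
                             key=lambda s: (s.objectives.size, -s.objectives.quality)))
    for a in solutions:  # front validity: no pairwise domination
        for b in solutions:
            if a is not b and dominates(a.objectives, b.objectives):
                raise AssertionError("returned front contains dominated solutions")
    return ParetoFront(solutions=solutions, generation_log=tuple(log),
                       n_unique_evaluations=cache.n_unique,
                       n_fitness_calls=cache.n_calls)


def report_front(front: ParetoFront, fm: "FeatureMatrix | None" = None) -> pd.DataFrame:
    """One row per front solution: size, CA, decoded params and names."""
    rows = []
    for s in front.solutions:
        rows.append({
            "size": s.objectives.size,
            "CA": round(s.objectives.quality, 2),
            "classifier": s.classifier.family,
            "params": ", ".join(f"{k}={v}" for k, v in s.classifier.params.items()),
            "selected": "[" + ", ".join(s.selected_names) + "]",
        })
    return pd.DataFrame(rows)


def selection_counts(front: ParetoFront) -> pd.DataFrame:
    """How often each channel/feature appears across the front's solutions."""
    counts: dict[str, int] = {}
    for s in front.solutions:
        for name in s.selected_names:
            counts[name] = counts.get(name, 0) + 1
    return (pd.DataFrame({"name": list(counts), "count": list(counts.values())})
            .sort_values(["count", "name"], ascending=[False, True])
            .reset_index(drop=True))
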