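"""Binary metaheuristic optimizers over gene-subset space.

Five population-based search algorithms — the Binary Bat Algorithm (BBA),
a Genetic Algorithm (GA), the Equilibrium Optimizer (EO), Cuckoo Search
(CSA) and the Red Deer Algorithm (RDA) — maximize one shared wrapper
fitness (:mod:`genefs.fitness`) over binary feature masks. BBA, GA, EO and
CSA project continuous positions to bits through the S-shaped sigmoid
transfer with a stochastic threshold; RDA thresholds its continuous
coordinates at 0.5 deterministically. Every optimizer keeps elitist
best-ever bookkeeping, so its convergence trace is non-decreasing, and all
randomness flows from one seeded generator per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gamma as gamma_fn
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .datasets import ExpressionDataset
from .fitness import FitnessConfig, FitnessEvaluator

__all__ = [
    "SubsetMask",
    "ConvergenceTrace",
    "OptimizerConfig",
    "sigmoid_transfer",
    "binarize_position",
    "rda_offspring",
    "BinaryBatSelector",
    "GeneticAlgorithmSelector",
    "EquilibriumOptimizerSelector",
    "CuckooSearchSelector",
    "RedDeerSelector",
    "ALGORITHMS",
    "make_selector",
    "optimize",
    "optimize_bba",
    "optimize_ga",
    "optimize_eo",
    "optimize_csa",
    "optimize_rda",
]


@dataclass
class SubsetMask:
    """A binary feature subset over the candidate gene pool."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)

    def gene_ids(self, pool_gene_ids) -> list:
        return [g for g, b in zip(pool_gene_ids, self.bits) if b]

    @property
    def size(self) -> int:
        return int(self.bits.sum())


@dataclass
class ConvergenceTrace:
    """Best-ever fitness (and mask) after initialization and each iteration."""

    best_fitness: list = field(default_factory=list)
    best_masks: list = field(default_factory=list)


def sigmoid_transfer(v):
    """S(v) = 1 / (1 + exp(-v)), overflow-safe, in (0, 1)."""
    return expit(v)


def binarize_position(v, rng) -> np.ndarray:
    """Bit j = 1 iff S(v_j) exceeds an independent U(0, 1) draw.

    An all-zero outcome is repaired by setting one uniformly chosen bit.
    """
    v = np.asarray(v, dtype=float)
    mask = sigmoid_transfer(v) > rng.random(v.size)
    return _repair(mask, rng)


def _repair(mask, rng) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool).copy()
    if not mask.any():
        mask[int(rng.integers(mask.size))] = True
    return mask


def reflect_bounds(x, lower: float, upper: float) -> np.ndarray:
    """Fold out-of-box coordinates back into [lower, upper] by reflection.

    Reflection keeps boundary coordinates mobile where clipping would pin
    them at the box edge (a pinned coordinate can never change its bit
    again under bounded local moves).
    """
    x = np.asarray(x, dtype=float).copy()
    span = upper - lower
    for _ in range(64):
        over = x > upper
        under = x < lower
        if not (over.any() or under.any()):
            break
        x[over] = 2 * upper - x[over]
        x[under] = 2 * lower - x[under]
    return np.clip(x, lower, upper)


def rda_offspring(com, hind, c, upper_bound: float = 5.0, lower_bound: float = -5.0):
    """Continuous red-deer recombinant: (Com + Hind) / 2 + (UB - LB) * c,
    reflected into the search bounds. With identical parents and c = 0 this
    is the parent itself, so the 0.5-threshold binarization reproduces the
    parent mask."""
    com = np.asarray(com, dtype=float)
    hind = np.asarray(hind, dtype=float)
    off = (com + hind) / 2.0 + (upper_bound - lower_bound) * c
    return reflect_bounds(off, lower_bound, upper_bound)


@dataclass
class OptimizerConfig:
    """Shared configuration for the five optimizers (reported defaults).

    Population and budget are common; the remaining fields are grouped per
    algorithm: loudness/pulse/decay/frequency bounds (BBA), crossover and
    mutation probabilities (GA), pool size and a1/a2/GP (EO), the nest
    abandonment fraction pa (CSA), and the role/bound parameters of RDA.
    ``omega`` is accepted for settings parity with the EO configuration but
    has no effect on the binary dynamics.
    """

    n_agents: int = 20
    max_iter: int = 100
    seed: int = 0
    # BBA
    loudness: float = 1.0
    pulse_rate: float = 0.15
    alpha: float = 0.95
    gamma: float = 0.5
    f_min: float = 0.0
    f_max: float = 2.0
    # GA
    crossover_rate: float = 0.4
    mutation_rate: float = 0.3
    # EO
    pool_size: int = 4
    a1: float = 2.0
    a2: float = 1.0
    generation_prob: float = 0.5
    omega: float = 0.9
    # CSA
    pa: float = 0.25
    # RDA
    male_fraction: float = 0.25
    commander_fraction: float = 0.5
    harem_mating_fraction: float = 0.2
    other_harem_fraction: float = 0.1
    upper_bound: float = 5.0
    lower_bound: float = -5.0


class _BaseMetaheuristicSelector(SelectorMixin, BaseEstimator):
    """Common machinery: fitness evaluator, elitist tracking, trace."""

    def __init__(self, n_agents=20, max_iter=100, weight=0.9, estimator=None,
                 cv=5, random_state=None, cache=None):
        self.n_agents = n_agents
        self.max_iter = max_iter
        self.weight = weight
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state
        self.cache = cache

    # -- template method ---------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_agents < 1:
            raise ValueError("n_agents must be at least 1")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        self.n_features_in_ = X.shape[1]
        config = FitnessConfig(weight=self.weight, estimator=self.estimator,
                               cv=self.cv)
        evaluator = FitnessEvaluator(X, y, config, cache=self.cache)
        rng = np.random.default_rng(self.random_state)

        self._best_fitness = -np.inf
        self._best_mask = None
        self._trace = ConvergenceTrace()
        self._optimize(evaluator, rng)

        self.support_ = self._best_mask.copy()
        # re-derive, never trust run-time bookkeeping
        self.best_fitness_ = float(evaluator(self.support_))
        self.trace_ = self._trace
        self.n_evaluations_ = evaluator.n_evaluations
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _track(self, fitness: float, mask: np.ndarray):
        # ties resolved like the exhaustive oracle: smaller subset first,
        # then lexicographically smallest index tuple
        if fitness > self._best_fitness:
            replace = True
        elif fitness == self._best_fitness and self._best_mask is not None:
            old = (int(self._best_mask.sum()), tuple(np.flatnonzero(self._best_mask)))
            new = (int(mask.sum()), tuple(np.flatnonzero(mask)))
            replace = new < old
        else:
            replace = False
        if replace:
            self._best_fitness = fitness
            self._best_mask = mask.copy()

    def _record(self):
        self._trace.best_fitness.append(self._best_fitness)
        self._trace.best_masks.append(self._best_mask.copy())

    def _init_population(self, n, rng):
        pop = rng.random((self.n_agents, n)) < 0.5
        return np.array([_repair(row, rng) for row in pop])

    def _optimize(self, evaluator, rng):  # pragma: no cover - abstract
        raise NotImplementedError


class BinaryBatSelector(_BaseMetaheuristicSelector):
    """Binary Bat Algorithm feature selector.

    Bats carry a binary position, a real velocity and a frequency drawn as
    f = f_min + (f_max - f_min) * beta with beta ~ U(0, 1); velocities move
    toward the global best and positions are re-binarized through the
    sigmoid transfer. A pulse-rate-gated local search perturbs the velocity
    with noise scaled by the mean loudness; acceptance of an improving
    candidate is gated by the bat's loudness, which then decays (A <- alpha
    * A) while the pulse rate grows (r <- r0 * (1 - exp(-gamma * t))).
    """

    def __init__(self, n_agents=20, max_iter=100, loudness=1.0, pulse_rate=0.15,
                 alpha=0.95, gamma=0.5, f_min=0.0, f_max=2.0, weight=0.9,
                 estimator=None, cv=5, random_state=None, cache=None):
        super().__init__(n_agents=n_agents, max_iter=max_iter, weight=weight,
                         estimator=estimator, cv=cv, random_state=random_state,
                         cache=cache)
        self.loudness = loudness
        self.pulse_rate = pulse_rate
        self.alpha = alpha
        self.gamma = gamma
        self.f_min = f_min
        self.f_max = f_max

    def _optimize(self, ev, rng):
        n = ev.n_features
        x = self._init_population(n, rng)
        v = np.zeros((self.n_agents, n))
        fits = np.array([ev(xi) for xi in x])
        for xi, fi in zip(x, fits):
            self._track(fi, xi)
        A = np.full(self.n_agents, float(self.loudness))
        r = np.full(self.n_agents, float(self.pulse_rate))
        self._record()
        for t in range(1, self.max_iter + 1):
            for i in range(self.n_agents):
                beta = rng.random()
                freq = self.f_min + (self.f_max - self.f_min) * beta
                v[i] = v[i] + (self._best_mask.astype(float) - x[i]) * freq
                cand = binarize_position(v[i], rng)
                if rng.random() > r[i]:
                    # local search around the best via a loudness-scaled kick
                    eps = rng.uniform(-1.0, 1.0, n) * A.mean()
                    cand = binarize_position(v[i] + eps, rng)
                fc = ev(cand)
                if rng.random() < A[i] and fc >= fits[i]:
                    x[i] = cand
                    fits[i] = fc
                    A[i] *= self.alpha
                    r[i] = self.pulse_rate * (1.0 - math.exp(-self.gamma * t))
                self._track(fc, cand)
            self._record()


class GeneticAlgorithmSelector(_BaseMetaheuristicSelector):
    """Genetic Algorithm over binary chromosomes.

    Roulette-wheel parent selection on min-shifted fitness, single-point
    crossover, independent per-bit mutation, elitism of one.
    """

    def __init__(self, n_agents=20, max_iter=100, crossover_rate=0.4,
                 mutation_rate=0.3, weight=0.9, estimator=None, cv=5,
                 random_state=None, cache=None):
        super().__init__(n_agents=n_agents, max_iter=max_iter, weight=weight,
                         estimator=estimator, cv=cv, random_state=random_state,
                         cache=cache)
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate

    def _optimize(self, ev, rng):
        n = ev.n_features
        pop = self._init_population(n, rng)
        fits = np.array([ev(c) for c in pop])
        for c, f in zip(pop, fits):
            self._track(f, c)
        self._record()
        for _ in range(self.max_iter):
            new_pop = [pop[int(np.argmax(fits))].copy()]  # elite
            shifted = fits - fits.min()
            total = shifted.sum()
            probs = shifted / total if total > 0 else np.full(len(fits), 1.0 / len(fits))
            while len(new_pop) < self.n_agents:
                i = int(rng.choice(self.n_agents, p=probs))
                j = int(rng.choice(self.n_agents, p=probs))
                c1, c2 = pop[i].copy(), pop[j].copy()
                if n > 1 and rng.random() < self.crossover_rate:
                    point = int(rng.integers(1, n))
                    c1[point:], c2[point:] = pop[j][point:].copy(), pop[i][point:].copy()
                for child in (c1, c2):
                    if len(new_pop) >= self.n_agents:
                        break
                    child = child ^ (rng.random(n) < self.mutation_rate)
                    new_pop.append(_repair(child, rng))
            pop = np.array(new_pop)
            fits = np.array([ev(c) for c in pop])
            for c, f in zip(pop, fits):
                self._track(f, c)
            self._record()


class EquilibriumOptimizerSelector(_BaseMetaheuristicSelector):
    """Binary Equilibrium Optimizer.

    Keeps an equilibrium pool of the ``pool_size`` best distinct solutions
    plus their mean; each agent relaxes toward a uniformly chosen pool
    member with an exponential term F built from a1, a2 and the iteration
    fraction, plus a generation-rate term gated by ``generation_prob``.
    Continuous concentrations are projected to bits by the sigmoid
    transfer. ``omega`` is carried for settings parity only.
    """

    def __init__(self, n_agents=20, max_iter=100, pool_size=4, a1=2.0, a2=1.0,
                 generation_prob=0.5, omega=0.9, weight=0.9, estimator=None,
                 cv=5, random_state=None, cache=None):
        super().__init__(n_agents=n_agents, max_iter=max_iter, weight=weight,
                         estimator=estimator, cv=cv, random_state=random_state,
                         cache=cache)
        self.pool_size = pool_size
        self.a1 = a1
        self.a2 = a2
        self.generation_prob = generation_prob
        self.omega = omega

    def _optimize(self, ev, rng):
        n = ev.n_features
        C = rng.uniform(-1.0, 1.0, (self.n_agents, n))
        pool = []  # list of (fitness, mask bytes, concentration vector)

        def update_pool(f, key, vec):
            for idx, (pf, pk, _) in enumerate(pool):
                if pk == key:
                    if f > pf:
                        pool[idx] = (f, key, vec.copy())
                    return
            pool.append((f, key, vec.copy()))
            pool.sort(key=lambda item: -item[0])
            del pool[self.pool_size:]

        fits = np.empty(self.n_agents)
        for i in range(self.n_agents):
            mask = binarize_position(C[i], rng)
            fits[i] = ev(mask)
            self._track(fits[i], mask)
            update_pool(fits[i], mask.tobytes(), C[i])
        self._record()

        for t in range(1, self.max_iter + 1):
            t_frac = (1.0 - t / self.max_iter) ** (self.a2 * t / self.max_iter)
            vectors = [vec for _, _, vec in pool]
            candidates = vectors + [np.mean(vectors, axis=0)]
            for i in range(self.n_agents):
                Ceq = candidates[int(rng.integers(len(candidates)))]
                r = rng.random(n)
                lam = rng.random(n)
                F = self.a1 * np.sign(r - 0.5) * (np.exp(-lam * t_frac) - 1.0)
                r1, r2 = rng.random(), rng.random()
                gcp = 0.5 * r1 if r2 >= self.generation_prob else 0.0
                G = gcp * (Ceq - lam * C[i]) * F
                with np.errstate(divide="ignore", invalid="ignore"):
                    C[i] = Ceq + (C[i] - Ceq) * F + np.where(lam > 0, G / lam, 0.0) * (1.0 - F)
                C[i] = np.clip(C[i], -50.0, 50.0)
                mask = binarize_position(C[i], rng)
                fits[i] = ev(mask)
                self._track(fits[i], mask)
                update_pool(fits[i], mask.tobytes(), C[i])
            self._record()


class CuckooSearchSelector(_BaseMetaheuristicSelector):
    """Binary Cuckoo Search with Mantegna Levy flights.

    One egg per nest; a new solution perturbs the nest's continuous
    position by a Levy-distributed step toward/away from the current best
    (exponent 1.5), is binarized through the sigmoid transfer, and replaces
    the nest greedily. Each iteration the worst ``pa`` fraction of
    non-elite nests is abandoned and re-initialized at random.
    """

    def __init__(self, n_agents=20, max_iter=100, pa=0.25, levy_exponent=1.5,
                 step_scale=0.01, init_scale=4.0, weight=0.9, estimator=None,
                 cv=5, random_state=None, cache=None):
        super().__init__(n_agents=n_agents, max_iter=max_iter, weight=weight,
                         estimator=estimator, cv=cv, random_state=random_state,
                         cache=cache)
        self.pa = pa
        self.levy_exponent = levy_exponent
        self.step_scale = step_scale
        self.init_scale = init_scale

    def _optimize(self, ev, rng):
        n = ev.n_features
        m = self.n_agents
        # init wide enough that the sigmoid transfer can saturate: positions
        # near 0 make every binarization a coin flip and the search cannot
        # exploit what it has found
        X = rng.uniform(-self.init_scale, self.init_scale, (m, n))
        masks = np.array([binarize_position(X[i], rng) for i in range(m)])
        fits = np.array([ev(mask) for mask in masks])
        for mask, f in zip(masks, fits):
            self._track(f, mask)
        self._record()

        beta = self.levy_exponent
        sigma_u = (
            gamma_fn(1 + beta) * math.sin(math.pi * beta / 2)
            / (gamma_fn((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)

        for _ in range(self.max_iter):
            ibest = int(np.argmax(fits))
            for i in range(m):
                u = rng.normal(0.0, sigma_u, n)
                v = rng.normal(0.0, 1.0, n)
                s = u / np.abs(v) ** (1 / beta)
                step = self.step_scale * s * (X[i] - X[ibest])
                x_new = X[i] + step * rng.normal(0.0, 1.0, n)
                m_new = binarize_position(x_new, rng)
                f_new = ev(m_new)
                self._track(f_new, m_new)
                if f_new >= fits[i]:
                    X[i], masks[i], fits[i] = x_new, m_new, f_new
            n_abandon = int(math.floor(self.pa * (m - 1)))
            if n_abandon:
                order = np.argsort(fits, kind="stable")  # worst first
                for i in order[:n_abandon]:
                    X[i] = rng.uniform(-self.init_scale, self.init_scale, n)
                    masks[i] = binarize_position(X[i], rng)
                    fits[i] = ev(masks[i])
                    self._track(fits[i], masks[i])
            self._record()


class RedDeerSelector(_BaseMetaheuristicSelector):
    """Binary Red Deer Algorithm.

    The sorted population splits into males (top ``male_fraction``) and
    hinds; the top ``commander_fraction`` of males are commanders, the rest
    stags. Males roar (a random local move kept only if it improves),
    commanders fight a random stag (the winner takes the commander slot),
    hinds are partitioned into harems proportional to commander fitness,
    and commanders mate with a fraction of their own harem
    (``harem_mating_fraction``) and of one other harem
    (``other_harem_fraction``). Offspring are the clipped continuous
    recombinant (Com + Hind)/2 + (UB - LB) * c thresholded at 0.5; the next
    generation is the elitist truncation of parents plus offspring.
    """

    def __init__(self, n_agents=20, max_iter=100, male_fraction=0.25,
                 commander_fraction=0.5, harem_mating_fraction=0.2,
                 other_harem_fraction=0.1, upper_bound=5.0, lower_bound=-5.0,
                 weight=0.9, estimator=None, cv=5, random_state=None, cache=None):
        super().__init__(n_agents=n_agents, max_iter=max_iter, weight=weight,
                         estimator=estimator, cv=cv, random_state=random_state,
                         cache=cache)
        self.male_fraction = male_fraction
        self.commander_fraction = commander_fraction
        self.harem_mating_fraction = harem_mating_fraction
        self.other_harem_fraction = other_harem_fraction
        self.upper_bound = upper_bound
        self.lower_bound = lower_bound

    def _mask_of(self, vec, rng):
        return _repair(vec > 0.5, rng)

    def _optimize(self, ev, rng):
        n = ev.n_features
        m = self.n_agents
        ub, lb = self.upper_bound, self.lower_bound
        V = rng.uniform(lb, ub, (m, n))
        masks = np.array([self._mask_of(V[i], rng) for i in range(m)])
        fits = np.array([ev(mask) for mask in masks])
        for mask, f in zip(masks, fits):
            self._track(f, mask)
        self._record()

        n_males = max(1, round(self.male_fraction * m))
        for _ in range(self.max_iter):
            order = np.argsort(-fits, kind="stable")
            V, masks, fits = V[order], masks[order], fits[order]

            # roaring: males probe nearby positions, keep improvements;
            # the offset r1 * ((UB - LB) * r2 + LB) is a symmetric random
            # move scaled into the search box
            for i in range(n_males):
                r1 = rng.random(n)
                r2 = rng.random(n)
                r3 = rng.random()
                delta = r1 * ((ub - lb) * r2 + lb)
                vc = V[i] + delta if r3 >= 0.5 else V[i] - delta
                vc = reflect_bounds(vc, lb, ub)
                mc = self._mask_of(vc, rng)
                fc = ev(mc)
                self._track(fc, mc)
                if fc > fits[i]:
                    V[i], masks[i], fits[i] = vc, mc, fc

            n_com = max(1, round(self.commander_fraction * n_males))
            n_com = min(n_com, n_males)
            n_stags = n_males - n_com
            if n_stags > 0:
                # a fight breeds two contender solutions from the pair; the
                # best of the four takes the commander slot
                for ci in range(n_com):
                    si = n_com + int(rng.integers(n_stags))
                    contenders = [
                        (fits[ci], V[ci].copy(), masks[ci].copy()),
                        (fits[si], V[si].copy(), masks[si].copy()),
                    ]
                    for _ in range(2):
                        vc = self._mate(V[ci], V[si], rng)
                        mc = self._mask_of(vc, rng)
                        fc = ev(mc)
                        self._track(fc, mc)
                        contenders.append((fc, vc, mc))
                    winner = max(range(4), key=lambda idx: contenders[idx][0])
                    if winner == 1:  # the stag takes the commander slot
                        V[[ci, si]] = V[[si, ci]]
                        masks[[ci, si]] = masks[[si, ci]]
                        fits[[ci, si]] = fits[[si, ci]]
                    elif winner > 1:
                        fw, vw, mw = contenders[winner]
                        V[ci], masks[ci], fits[ci] = vw, mw, fw

            hinds = np.arange(n_males, m)
            offspring = []
            if hinds.size and n_com:
                shuffled = rng.permutation(hinds)
                sizes = self._harem_sizes(fits[:n_com], hinds.size)
                harems, start = [], 0
                for size in sizes:
                    harems.append(shuffled[start:start + size])
                    start += size
                for ci in range(n_com):
                    own = harems[ci]
                    n_own = round(self.harem_mating_fraction * own.size)
                    if n_own:
                        chosen = rng.choice(own.size, size=n_own, replace=False)
                        for h in own[chosen]:
                            offspring.append(self._mate(V[ci], V[h], rng))
                    if n_com > 1:
                        cj = (ci + 1 + int(rng.integers(n_com - 1))) % n_com
                        other = harems[cj]
                        n_other = round(self.other_harem_fraction * other.size)
                        if n_other:
                            chosen = rng.choice(other.size, size=n_other, replace=False)
                            for h in other[chosen]:
                                offspring.append(self._mate(V[ci], V[h], rng))

            if offspring:
                off_V = np.array(offspring)
                off_masks = np.array([self._mask_of(v, rng) for v in off_V])
                off_fits = np.array([ev(mask) for mask in off_masks])
                for mask, f in zip(off_masks, off_fits):
                    self._track(f, mask)
                V = np.vstack([V, off_V])
                masks = np.vstack([masks, off_masks])
                fits = np.concatenate([fits, off_fits])
                # elitist truncation over distinct masks: keeping duplicate
                # copies of the incumbent collapses diversity within a few
                # generations
                order = np.argsort(-fits, kind="stable")
                keep, seen = [], set()
                for idx in order:
                    key = masks[idx].tobytes()
                    if key not in seen:
                        seen.add(key)
                        keep.append(idx)
                    if len(keep) == m:
                        break
                if len(keep) < m:
                    extras = [idx for idx in order if idx not in set(keep)]
                    keep.extend(extras[: m - len(keep)])
                keep = np.array(keep)
                V, masks, fits = V[keep], masks[keep], fits[keep]
            self._record()

    def _mate(self, com, hind, rng):
        c = rng.random()
        return rda_offspring(com, hind, c, self.upper_bound, self.lower_bound)

    @staticmethod
    def _harem_sizes(commander_fits, n_hinds):
        """Largest-remainder allocation proportional to min-shifted fitness."""
        w = commander_fits - commander_fits.min()
        total = w.sum()
        if total <= 0:
            w = np.ones_like(commander_fits)
            total = w.sum()
        raw = w / total * n_hinds
        sizes = np.floor(raw).astype(int)
        remainder = n_hinds - sizes.sum()
        if remainder > 0:
            frac_order = np.argsort(-(raw - sizes), kind="stable")
            for idx in frac_order[:remainder]:
                sizes[idx] += 1
        return sizes


ALGORITHMS = {
    "bba": BinaryBatSelector,
    "ga": GeneticAlgorithmSelector,
    "eo": EquilibriumOptimizerSelector,
    "csa": CuckooSearchSelector,
    "rda": RedDeerSelector,
}

_ALGO_PARAMS = {
    "bba": ("loudness", "pulse_rate", "alpha", "gamma", "f_min", "f_max"),
    "ga": ("crossover_rate", "mutation_rate"),
    "eo": ("pool_size", "a1", "a2", "generation_prob", "omega"),
    "csa": ("pa",),
    "rda": ("male_fraction", "commander_fraction", "harem_mating_fraction",
            "other_harem_fraction", "upper_bound", "lower_bound"),
}


def make_selector(algorithm: str, fit: FitnessConfig = None,
                  opt: OptimizerConfig = None, cache: dict = None):
    """Build the selector estimator for ``algorithm`` from config objects."""
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    fit = fit or FitnessConfig()
    opt = opt or OptimizerConfig()
    kwargs = {name: getattr(opt, name) for name in _ALGO_PARAMS[algorithm]}
    return ALGORITHMS[algorithm](
        n_agents=opt.n_agents,
        max_iter=opt.max_iter,
        weight=fit.weight,
        estimator=fit.estimator,
        cv=fit.cv,
        random_state=opt.seed,
        cache=cache,
        **kwargs,
    )


def optimize(dataset: ExpressionDataset, algorithm: str,
             fit: FitnessConfig = None, opt: OptimizerConfig = None,
             cache: dict = None):
    """Run one optimizer on a dataset; returns ``(SubsetMask, ConvergenceTrace)``."""
    selector = make_selector(algorithm, fit, opt, cache)
    selector.fit(dataset.values, dataset.labels)
    return SubsetMask(selector.support_.copy()), selector.trace_


def optimize_bba(dataset, fit=None, opt=None, cache=None):
    return optimize(dataset, "bba", fit, opt, cache)


def optimize_ga(dataset, fit=None, opt=None, cache=None):
    return optimize(dataset, "ga", fit, opt, cache)


def optimize_eo(dataset, fit=None, opt=None, cache=None):
    return optimize(dataset, "eo", fit, opt, cache)


def optimize_csa(dataset, fit=None, opt=None, cache=None):
    return optimize(dataset, "csa", fit, opt, cache)


def optimize_rda(dataset, fit=None, opt=None, cache=None):
    return optimize(dataset, "rda", fit, opt, cache)
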