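"""Genetic-algorithm fusion of the six base predictors.

The six per-residue probability tracks (order: DARTS, CAN, HAN,
IDP-Seq2Seq, CNN-LSTM, LSTM-CNN) are combined linearly,

    p_fused[i] = sum_k w_k * p_k[i],   w_k >= 0,  sum_k w_k = 1,

and the weight vector is optimized by a real-coded genetic algorithm
whose fitness is the AUC of the fused track summed over several
validation datasets with different SDR:LDR compositions. Summing over
ratio-stratified datasets (rather than maximizing AUC on one pooled
set) is what makes the fused predictor stable under unknown
short/long-disorder mixtures. A Pareto per-dataset mode is available
behind a flag; the scalar sum is the default fitness.

AUC is invariant to the overall scale of the weights, so constraining
them to the probability simplex loses nothing and keeps the fused
output a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DataError, ParameterError
from .evaluation import auc
from .types import PredictionTrack

#: Fixed base-method order of the weight vector.
METHOD_ORDER = ("DARTS", "CAN", "HAN", "SEQ2SEQ", "CNN_LSTM", "LSTM_CNN")
N_METHODS = len(METHOD_ORDER)


@dataclass
class WeightVector:
    """Six nonnegative fusion weights on the probability simplex."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_METHODS,):
            raise ContractError(f"expected {N_METHODS} weights, got shape {self.values.shape}")
        if (self.values < -1e-12).any():
            raise ContractError("fusion weights must be nonnegative")
        total = self.values.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ContractError(f"fusion weights must sum to 1, got {total}")

    @classmethod
    def uniform(cls) -> "WeightVector":
        return cls(np.full(N_METHODS, 1.0 / N_METHODS))

    @classmethod
    def one_hot(cls, index: int) -> "WeightVector":
        v = np.zeros(N_METHODS)
        v[index] = 1.0
        return cls(v)

    def as_dict(self) -> dict:
        return dict(zip(METHOD_ORDER, self.values.tolist()))


@dataclass
class ValidationDataset:
    """One labeled validation dataset: per protein, the label track and
    its six base-predictor tracks, plus the dataset's SDR:LDR tag."""

    name: str
    labels: list  # per protein: np.ndarray of 0/1
    tracks: list  # per protein: (6, L) np.ndarray, rows in METHOD_ORDER
    ratio: tuple = (1, 1)

    def __post_init__(self):
        if len(self.labels) != len(self.tracks):
            raise ContractError(f"dataset {self.name!r}: labels/tracks count mismatch")
        for idx, (y, t) in enumerate(zip(self.labels, self.tracks)):
            t = np.asarray(t, dtype=float)
            if t.shape != (N_METHODS, len(y)):
                raise ContractError(
                    f"dataset {self.name!r}, protein {idx}: tracks have shape "
                    f"{t.shape}, expected ({N_METHODS}, {len(y)})"
                )
            self.tracks[idx] = t

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All residues pooled: (labels, (R, 6) score matrix)."""
        y = np.concatenate([np.asarray(v) for v in self.labels])
        scores = np.concatenate([t.T for t in self.tracks], axis=0)
        return y, scores


@dataclass
class ValidationSuite:
    datasets: list

    def __post_init__(self):
        if not self.datasets:
            raise ContractError("a validation suite needs at least one dataset")

    def __len__(self):
        return len(self.datasets)


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.05
    elitism: int = 2
    tournament: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ParameterError("population must be >= 2")
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ParameterError("elitism must be in [0, population)")


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def fuse(tracks, weights: WeightVector, record_id: str = "fused") -> PredictionTrack:
    """Weighted per-residue sum of six probability tracks."""
    arrays = []
    for k, track in enumerate(tracks):
        arr = track.probabilities if isinstance(track, PredictionTrack) else np.asarray(track, float)
        arrays.append(arr)
    if len(arrays) != N_METHODS:
        raise ContractError(f"expected {N_METHODS} tracks, got {len(arrays)}")
    L = arrays[0].size
    for k, arr in enumerate(arrays):
        if arr.size != L:
            raise ContractError(f"track {k} has length {arr.size}, expected {L}")
    fused = np.zeros(L)
    for w, arr in zip(weights.values, arrays):
        fused += w * arr
    return PredictionTrack(id=record_id, probabilities=np.clip(fused, 0.0, 1.0))


def average_fusion(tracks, record_id: str = "fused") -> PredictionTrack:
    """The baseline strategy: per-residue arithmetic mean of the six tracks."""
    return fuse(tracks, WeightVector.uniform(), record_id=record_id)


def per_dataset_auc(weights: WeightVector, suite: ValidationSuite) -> np.ndarray:
    values = []
    for ds in suite.datasets:
        y, scores = ds.pooled()
        if len(np.unique(y)) < 2:
            raise DataError(
                f"dataset {ds.name!r} has a single label class; AUC undefined"
            )
        values.append(auc(scores @ weights.values, y))
    return np.array(values)


def fitness(weights: WeightVector, suite: ValidationSuite) -> float:
    """Sum over the suite's datasets of the fused-track AUC (pooled residues)."""
    return float(per_dataset_auc(weights, suite).sum())


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class GAResult:
    best: WeightVector
    best_fitness: float
    trajectory: list = field(default_factory=list)
    pareto: list | None = None


def ga_optimize(suite: ValidationSuite, config: GAConfig | None = None,
                pareto: bool = False) -> GAResult:
    """Optimize the fusion weights by a real-coded GA.

    Tournament selection, blend (BLX-0.5) crossover, Gaussian mutation and
    elitism; every candidate is projected back onto the simplex after
    variation, so all evaluated vectors are valid weightings. The best
    fitness is non-decreasing across generations (elitism). With
    ``pareto=True`` the per-dataset AUC vectors of the final population's
    non-dominated candidates are also returned.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)

    # precompute pooled scores per dataset once; fitness is then cheap
    pooled = []
    for ds in suite.datasets:
        y, scores = ds.pooled()
        if len(np.unique(y)) < 2:
            raise DataError(f"dataset {ds.name!r} has a single label class; AUC undefined")
        pooled.append((y, scores))

    def evaluate(vec: np.ndarray) -> float:
        return float(sum(auc(scores @ vec, y) for y, scores in pooled))

    pop = [project_simplex(rng.dirichlet(np.ones(N_METHODS))) for _ in range(config.population)]
    fits = np.array([evaluate(v) for v in pop])
    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trajectory = [best_fit]

    for _gen in range(config.generations):
        elite_order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in elite_order[: config.elitism]]
        while len(new_pop) < config.population:
            contenders = rng.integers(0, config.population, size=config.tournament)
            p1 = pop[contenders[np.argmax(fits[contenders])]]
            contenders = rng.integers(0, config.population, size=config.tournament)
            p2 = pop[contenders[np.argmax(fits[contenders])]]
            child = p1.copy()
            if rng.random() < config.crossover_prob:
                gamma = rng.uniform(-0.5, 1.5, size=N_METHODS)
                child = gamma * p1 + (1.0 - gamma) * p2
            if rng.random() < config.mutation_prob:
                child = child + rng.normal(0.0, config.mutation_sigma, size=N_METHODS)
            new_pop.append(project_simplex(child))
        pop = new_pop
        fits = np.array([evaluate(v) for v in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        trajectory.append(best_fit)

    result = GAResult(best=WeightVector(best), best_fitness=best_fit, trajectory=trajectory)
    if pareto:
        objective_vectors = [
            np.array([auc(scores @ v, y) for y, scores in pooled]) for v in pop
        ]
        front = []
        for a, obj_a in enumerate(objective_vectors):
            dominated = any(
                b != a and (objective_vectors[b] >= obj_a).all()
                and (objective_vectors[b] > obj_a).any()
                for b in range(len(pop))
            )
            if not dominated:
                front.append((WeightVector(pop[a]), obj_a))
        result.pareto = front
    return result


def write_weights(weights: WeightVector, path, seed: int | None = None,
                  fingerprint: str | None = None) -> None:
    """Serialize weights as a small keyed text file."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if fingerprint is not None:
            fh.write(f"# suite: {fingerprint}\n")
        for name, value in weights.as_dict().items():
            fh.write(f"{name}\t{value:.6f}\n")


def read_weights(path) -> WeightVector:
    values = dict.fromkeys(METHOD_ORDER, 0.0)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, value = line.split()
            values[name] = float(value)
    vec = np.array([values[name] for name in METHOD_ORDER])
    return WeightVector(vec / vec.sum())
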