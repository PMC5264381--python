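"""Ordinal grade classifier: a small feed-forward network whose topology and
training hyperparameters are chosen by an island-model genetic algorithm.

The network is a 1- or 2-hidden-layer perceptron with a 3-way softmax head,
trained by seeded mini-batch gradient descent with momentum on the
cross-entropy loss.  The genetic algorithm searches genome space (layer
sizes, activation, learning rate, momentum, epoch budget, weight seed) with
tournament selection, uniform crossover, per-gene mutation, per-island
elitism and ring migration; fitness is exact validation accuracy.  The best
genome is finally retrained on the training split and judged once on the
untouched blind-test split, reporting exact agreement with the examiner
consensus and the count of critical (two-grade) errors.

All randomness fans out from one master seed through named substreams, so
an entire evolve-train-evaluate chain is bit-for-bit reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (ConfigurationError, DivergenceError, SchemaError,
                     StratificationError)

GRADES = (1, 2, 3)
BATCH_SIZE = 16
ACTIVATIONS = ("logistic", "tanh", "relu")
HIDDEN_RANGE = (2, 64)
LR_RANGE = (1e-3, 0.3)          # log-uniform
MOMENTUM_RANGE = (0.0, 0.95)
EPOCH_RANGE = (30, 200)


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed from a master seed and string/int tags."""
    ints = [master] + [t if isinstance(t, int) else zlib.crc32(str(t).encode())
                       for t in tags]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    valid_fraction: float = 0.15
    test_fraction: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        total = self.train_fraction + self.valid_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if min(self.train_fraction, self.valid_fraction,
               self.test_fraction) <= 0:
            raise ConfigurationError("every split fraction must be positive")


def largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer split sizes summing to n: floors first, then +1 to the
    largest fractional remainders (ties to the earlier split)."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    short = n - sum(sizes)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split_dataset(n: int, spec: SplitSpec,
                  labels: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/validation/test index sets covering 0..n-1.

    Sizes follow largest-remainder rounding of the fractions; with
    stratification, class members are spread over the splits in proportion
    while preserving the exact global sizes.
    """
    if n < 10:
        raise ConfigurationError("need at least 10 samples to split")
    fracs = (spec.train_fraction, spec.valid_fraction, spec.test_fraction)
    sizes = largest_remainder_sizes(n, fracs)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified or labels is None:
        perm = rng.permutation(n)
        tr = perm[:sizes[0]]
        va = perm[sizes[0]:sizes[0] + sizes[1]]
        te = perm[sizes[0] + sizes[1]:]
        return np.sort(tr), np.sort(va), np.sort(te)

    labels = np.asarray(labels)
    if len(labels) != n:
        raise SchemaError("labels length must equal n")
    buckets: list[list[int]] = [[], [], []]
    classes = np.unique(labels)
    for cls in classes:
        members = rng.permutation(np.flatnonzero(labels == cls))
        if len(members) < 3:
            raise StratificationError(
                f"class {cls} has {len(members)} members; cannot appear "
                f"in every split")
        csizes = largest_remainder_sizes(len(members), fracs)
        # guarantee representation of the class in every split
        for b in range(3):
            if csizes[b] == 0:
                donor = int(np.argmax(csizes))
                csizes[donor] -= 1
                csizes[b] += 1
        start = 0
        for b in range(3):
            buckets[b].extend(members[start:start + csizes[b]])
            start += csizes[b]
    # reconcile per-class rounding drift with the exact global sizes
    for b in range(3):
        while len(buckets[b]) > sizes[b]:
            for b2 in range(3):
                if len(buckets[b2]) < sizes[b2]:
                    buckets[b2].append(buckets[b].pop())
                    break
    for b in range(3):
        if len(buckets[b]) != sizes[b]:
            raise StratificationError("could not reconcile stratified sizes")
    tr, va, te = (np.sort(np.array(b, dtype=int)) for b in buckets)
    return tr, va, te


# ---------------------------------------------------------------------------
# network

@dataclass(frozen=True)
class ANNGenome:
    n_hidden_layers: int = 1
    hidden_sizes: tuple[int, ...] = (16,)
    activation: str = "tanh"
    learning_rate: float = 0.05
    momentum: float = 0.5
    epochs: int = 100
    weight_seed: int = 0

    def __post_init__(self):
        if self.n_hidden_layers not in (1, 2):
            raise ConfigurationError("n_hidden_layers must be 1 or 2")
        if len(self.hidden_sizes) != self.n_hidden_layers:
            raise ConfigurationError("hidden_sizes length mismatch")
        for h in self.hidden_sizes:
            if not HIDDEN_RANGE[0] <= h <= HIDDEN_RANGE[1]:
                raise ConfigurationError("hidden size out of range")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must lie in [0, 1)")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be non-negative")

    def as_tuple(self) -> tuple:
        h2 = self.hidden_sizes[1] if self.n_hidden_layers == 2 else 0
        return (self.n_hidden_layers, self.hidden_sizes[0], h2,
                self.activation, round(self.learning_rate, 10),
                round(self.momentum, 10), self.epochs, self.weight_seed)


@dataclass
class TrainedANN:
    genome: ANNGenome
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    train_loss_curve: list[float] = field(default_factory=list)
    input_dim: int = 24
    output_dim: int = 3


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    if kind == "tanh":
        return np.tanh(z)
    return np.maximum(z, 0.0)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return a * (1.0 - a)
    if kind == "tanh":
        return 1.0 - a**2
    return (a > 0).astype(float)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_layers(genome: ANNGenome, input_dim: int
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    rng = np.random.default_rng(genome.weight_seed)
    dims = [input_dim, *genome.hidden_sizes, len(GRADES)]
    W, b = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        scale = np.sqrt(2.0 / fan_in) if genome.activation == "relu" \
            else np.sqrt(1.0 / fan_in)
        W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        b.append(np.zeros(fan_out))
    return W, b


def _forward(X: np.ndarray, W: list[np.ndarray], b: list[np.ndarray],
             activation: str) -> list[np.ndarray]:
    acts = [X]
    for li in range(len(W) - 1):
        acts.append(_act(acts[-1] @ W[li] + b[li], activation))
    acts.append(_softmax(acts[-1] @ W[-1] + b[-1]))
    return acts


def train_ann(genome: ANNGenome, X: np.ndarray, y: np.ndarray) -> TrainedANN:
    """Mini-batch gradient descent with momentum on softmax cross-entropy.

    Inputs are z-scored with statistics fitted here (on the training rows
    only) and stored in the model.  Deterministic for a fixed genome and
    data: weight init and batch shuffling derive from the genome seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise SchemaError("non-finite inputs")
    if not np.isin(y, GRADES).all():
        raise SchemaError("labels must lie in {1,2,3}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    Y = np.eye(len(GRADES))[y - 1]

    W, b = _init_layers(genome, X.shape[1])
    vW = [np.zeros_like(w) for w in W]
    vb = [np.zeros_like(bb) for bb in b]
    rng = np.random.default_rng(derive_seed(genome.weight_seed, "batches"))
    n = len(Xs)
    curve: list[float] = []
    for _epoch in range(genome.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, BATCH_SIZE):
            idx = order[start:start + BATCH_SIZE]
            xb, yb = Xs[idx], Y[idx]
            acts = _forward(xb, W, b, genome.activation)
            probs = acts[-1]
            loss = float(-np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1)))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"training diverged (learning_rate={genome.learning_rate})")
            losses.append(loss)
            delta = (probs - yb) / len(xb)
            for li in range(len(W) - 1, -1, -1):
                gW = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ W[li].T) * _act_grad(acts[li],
                                                          genome.activation)
                vW[li] = genome.momentum * vW[li] - genome.learning_rate * gW
                vb[li] = genome.momentum * vb[li] - genome.learning_rate * gb
                W[li] = W[li] + vW[li]
                b[li] = b[li] + vb[li]
        curve.append(float(np.mean(losses)))
    return TrainedANN(genome=genome, weights=W, biases=b, scaler_mean=mean,
                      scaler_sd=sd, train_loss_curve=curve,
                      input_dim=X.shape[1], output_dim=len(GRADES))


def predict_proba(model: TrainedANN, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise SchemaError(
            f"expected {model.input_dim} inputs, got {X.shape[1]}")
    Xs = (X - model.scaler_mean) / model.scaler_sd
    return _forward(Xs, model.weights, model.biases,
                    model.genome.activation)[-1]


def predict_grade(model: TrainedANN, x: np.ndarray
                  ) -> tuple[int, np.ndarray] | tuple[np.ndarray, np.ndarray]:
    """Grade = argmax of the softmax posterior, ties broken toward the
    lower grade; returns (grade(s), probabilities)."""
    probs = predict_proba(model, x)
    grades = np.argmax(probs, axis=1) + 1  # argmax takes the first = lowest
    if np.asarray(x).ndim == 1:
        return int(grades[0]), probs[0]
    return grades, probs


# ---------------------------------------------------------------------------
# genetic algorithm

@dataclass(frozen=True)
class GAConfig:
    n_islands: int = 2
    island_size: int = 10
    generations: int = 20
    tournament_k: int = 3
    crossover_p: float = 0.5
    mutation_p: float = 0.1
    migration_interval: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.island_size < 4:
            raise ConfigurationError("population must be >= 4 per island")
        if self.generations < 1:
            raise ConfigurationError("need at least one generation")


@dataclass
class Population:
    islands: list[list[ANNGenome]]
    fitness: list[list[float]]
    generation: int
    rng_seed: int
    best_history: list[float] = field(default_factory=list)


_GENE_NAMES = ("n_hidden_layers", "h1", "h2", "activation", "learning_rate",
               "momentum", "epochs", "weight_seed")


def _random_gene(name: str, rng: np.random.Generator):
    if name == "n_hidden_layers":
        return int(rng.integers(1, 3))
    if name in ("h1", "h2"):
        return int(rng.integers(HIDDEN_RANGE[0], HIDDEN_RANGE[1] + 1))
    if name == "activation":
        return str(rng.choice(ACTIVATIONS))
    if name == "learning_rate":
        lo, hi = np.log(LR_RANGE)
        return float(np.exp(rng.uniform(lo, hi)))
    if name == "momentum":
        return float(rng.uniform(*MOMENTUM_RANGE))
    if name == "epochs":
        return int(rng.integers(EPOCH_RANGE[0], EPOCH_RANGE[1] + 1))
    return int(rng.integers(0, 2**31 - 1))


def _random_genome(rng: np.random.Generator) -> ANNGenome:
    genes = {g: _random_gene(g, rng) for g in _GENE_NAMES}
    return _genes_to_genome(genes)


def _genes_to_genome(genes: dict) -> ANNGenome:
    nh = genes["n_hidden_layers"]
    hidden = (genes["h1"],) if nh == 1 else (genes["h1"], genes["h2"])
    return ANNGenome(n_hidden_layers=nh, hidden_sizes=hidden,
                     activation=genes["activation"],
                     learning_rate=genes["learning_rate"],
                     momentum=genes["momentum"], epochs=genes["epochs"],
                     weight_seed=genes["weight_seed"])


def _genome_to_genes(g: ANNGenome) -> dict:
    return {"n_hidden_layers": g.n_hidden_layers,
            "h1": g.hidden_sizes[0],
            "h2": g.hidden_sizes[1] if g.n_hidden_layers == 2
                  else g.hidden_sizes[0],
            "activation": g.activation, "learning_rate": g.learning_rate,
            "momentum": g.momentum, "epochs": g.epochs,
            "weight_seed": g.weight_seed}


def _crossover(a: ANNGenome, b: ANNGenome, p: float,
               rng: np.random.Generator) -> ANNGenome:
    ga, gb = _genome_to_genes(a), _genome_to_genes(b)
    child = {k: (gb[k] if rng.random() < p else ga[k]) for k in _GENE_NAMES}
    return _genes_to_genome(child)


def _mutate(g: ANNGenome, p: float, rng: np.random.Generator) -> ANNGenome:
    genes = _genome_to_genes(g)
    for k in _GENE_NAMES:
        if rng.random() < p:
            genes[k] = _random_gene(k, rng)
    return _genes_to_genome(genes)


def exact_accuracy(model: TrainedANN, X: np.ndarray, y: np.ndarray) -> float:
    grades, _ = predict_grade(model, np.atleast_2d(X))
    return float(np.mean(grades == np.asarray(y)))


def ga_evolve(config: GAConfig, X_train: np.ndarray, y_train: np.ndarray,
              X_valid: np.ndarray, y_valid: np.ndarray
              ) -> tuple[ANNGenome, TrainedANN, Population]:
    """Island-model evolution of ANN genomes.

    Fitness is exact validation accuracy of the trained genome (ties in
    selection favour the earlier individual).  Per island and generation:
    elitism (best genome kept unchanged), tournament selection (k=3),
    uniform crossover, per-gene mutation; every ``migration_interval``
    generations the best genome of each island replaces the worst of the
    next island on a ring.  Returns the overall best genome retrained on
    the training split.
    """
    if len(X_valid) == 0:
        raise ConfigurationError("empty validation split")
    rng = np.random.default_rng(derive_seed(config.seed, "ga"))
    cache: dict[tuple, float] = {}

    def fitness(genome: ANNGenome) -> float:
        key = genome.as_tuple()
        if key not in cache:
            model = train_ann(genome, X_train, y_train)
            cache[key] = exact_accuracy(model, X_valid, y_valid)
        return cache[key]

    islands = [[_random_genome(rng) for _ in range(config.island_size)]
               for _ in range(config.n_islands)]
    pop = Population(islands=islands, fitness=[], generation=0,
                     rng_seed=config.seed)

    best_genome, best_fit = None, -1.0
    for gen in range(config.generations):
        fits = [[fitness(g) for g in isl] for isl in pop.islands]
        pop.fitness = fits
        for isl, fi in zip(pop.islands, fits):
            i_best = int(np.argmax(fi))
            if fi[i_best] > best_fit:
                best_fit, best_genome = fi[i_best], isl[i_best]
        pop.best_history.append(best_fit)

        new_islands = []
        for isl, fi in zip(pop.islands, fits):
            elite = isl[int(np.argmax(fi))]
            children = [elite]
            while len(children) < config.island_size:
                def tournament():
                    idx = rng.choice(len(isl), size=config.tournament_k,
                                     replace=False)
                    return isl[int(idx[np.argmax([fi[i] for i in idx])])]
                child = _crossover(tournament(), tournament(),
                                   config.crossover_p, rng)
                children.append(_mutate(child, config.mutation_p, rng))
            new_islands.append(children)

        if config.n_islands > 1 and (gen + 1) % config.migration_interval == 0:
            migrants = []
            for isl in new_islands:
                fi = [fitness(g) for g in isl]
                migrants.append(isl[int(np.argmax(fi))])
            for k, isl in enumerate(new_islands):
                fi = [fitness(g) for g in isl]
                isl[int(np.argmin(fi))] = migrants[(k - 1) % len(new_islands)]

        pop.islands = new_islands
        pop.generation = gen + 1

    # final sweep so late arrivals count
    fits = [[fitness(g) for g in isl] for isl in pop.islands]
    pop.fitness = fits
    for isl, fi in zip(pop.islands, fits):
        i_best = int(np.argmax(fi))
        if fi[i_best] > best_fit:
            best_fit, best_genome = fi[i_best], isl[i_best]
    pop.best_history.append(best_fit)

    best_model = train_ann(best_genome, X_train, y_train)
    return best_genome, best_model, pop


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    exact_accuracy: float
    confusion: np.ndarray          # rows: consensus grade, cols: predicted
    critical_errors: int
    n_test: int

    def to_dict(self) -> dict:
        return {"exact_accuracy": self.exact_accuracy,
                "confusion": self.confusion.tolist(),
                "critical_errors": self.critical_errors,
                "n_test": self.n_test}


def evaluate_blind(model: TrainedANN, X_test: np.ndarray,
                   y_test: np.ndarray) -> EvalReport:
    """Exact agreement with the consensus labels on the blind split.

    A critical error is a two-grade miss (excellent/good confused with
    poor): |predicted - consensus| >= 2 on the 3-point scale.
    """
    y = np.asarray(y_test, dtype=int)
    grades, _ = predict_grade(model, np.atleast_2d(X_test))
    confusion = np.zeros((3, 3), dtype=int)
    for t, p in zip(y, grades):
        confusion[t - 1, p - 1] += 1
    critical = int(confusion[0, 2] + confusion[2, 0])
    return EvalReport(exact_accuracy=float(np.mean(grades == y)),
                      confusion=confusion, critical_errors=critical,
                      n_test=len(y))
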