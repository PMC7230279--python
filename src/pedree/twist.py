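"""TWIST: joint evolutionary selection of variables and a matched A/B split.

A wrapper feature selector: each genome carries (i) a boolean mask over
the candidate variables and (ii) an A/B label per record. Fitness is the
*generalisation* of the downstream perceptron under the frozen-weights
two-run protocol — train on A, test on B, then the reverse — minus a small
parsimony penalty per active variable, so ties break toward smaller
variable sets. Evolving the split together with the mask pushes the two
subsets toward similar distributions: a lopsided split scores badly in at
least one direction.

The evolutionary engine is a standard generational GA — tournament
selection (k = 2), uniform crossover on both chromosome parts, bit-flip
mutation on the mask, A↔B label swaps on the split (count-preserving),
elitism — behind a small interface so alternative strategies can be
plugged in. The proprietary "genetic doping" operators of the original
TWIST implementation are not published; this engine is a documented
approximation, not a replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, DataContractError
from .mlp import MlpSettings, two_run_protocol


@dataclass(frozen=True)
class TwistConfig:
    """GA and fitness parameters."""

    population_size: int = 16
    generations: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float | None = None   # None -> 1/L per gene
    elitism: int = 2
    parsimony_weight: float = 0.5        # score units (kcal/day) per active variable
    imbalance_cap_frac: float = 0.05     # |#A - #B| <= cap_frac * n
    seed: int = 0
    mlp_hidden: int = 4
    mlp_epochs: int = 200                # reduced inside the GA loop
    mlp_learning_rate: float = 0.05
    mlp_momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise InvalidConfigError("population_size must be >= 4")
        if not 0 <= self.crossover_rate <= 1:
            raise InvalidConfigError("crossover_rate must be in [0,1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise InvalidConfigError("mutation_rate must be in [0,1]")
        if self.elitism >= self.population_size:
            raise InvalidConfigError("elitism must be < population_size")


@dataclass
class TwistGenome:
    """One candidate solution: variable mask + record split."""

    variable_mask: np.ndarray    # (N,) bool
    split_a: np.ndarray          # (n,) bool, True -> subset A

    def key(self) -> bytes:
        return self.variable_mask.tobytes() + self.split_a.tobytes()


@dataclass
class TwistResult:
    """Decoded best genome plus the run's audit trail."""

    selected_variables: list[str]
    subset_a_ids: list
    subset_b_ids: list
    best_fitness_history: list[float]
    split_similarity: dict[str, float]   # per-variable two-sample KS statistic
    best_fitness: float
    evaluations: int

    def to_json_dict(self) -> dict:
        return {
            "selected_variables": self.selected_variables,
            "subset_a_ids": list(self.subset_a_ids),
            "subset_b_ids": list(self.subset_b_ids),
            "best_fitness_history": self.best_fitness_history,
            "split_similarity": self.split_similarity,
            "best_fitness": self.best_fitness,
            "evaluations": self.evaluations,
        }


def _is_degenerate(genome: TwistGenome, cap: int) -> bool:
    n_a = int(genome.split_a.sum())
    n_b = len(genome.split_a) - n_a
    return (
        genome.variable_mask.sum() < 2
        or n_a < 2 or n_b < 2
        or abs(n_a - n_b) > cap
    )


def evaluate_fitness(
    genome: TwistGenome,
    features: np.ndarray,
    targets: np.ndarray,
    settings_base: MlpSettings,
    parsimony_weight: float,
    imbalance_cap: int,
) -> float:
    """Two-run testing MAE (negated), minus the parsimony penalty.

    Degenerate genomes (fewer than 2 variables, an unusable or lopsided
    split) score −inf and are never selected.
    """
    if _is_degenerate(genome, imbalance_cap):
        return -math.inf
    cols = np.nonzero(genome.variable_mask)[0]
    a = genome.split_a
    fa, fb = features[a][:, cols], features[~a][:, cols]
    ya, yb = targets[a], targets[~a]
    from dataclasses import replace
    settings = replace(settings_base, n_inputs=len(cols))
    report = two_run_protocol(fa, ya, fb, yb, settings)
    mean_test_mae = 0.5 * (report.metrics_ab.mae + report.metrics_ba.mae)
    return -mean_test_mae - parsimony_weight * float(len(cols))


def split_similarity(features: pd.DataFrame, subset_a_ids, subset_b_ids) -> dict[str, float]:
    """Kolmogorov–Smirnov statistic per variable between subsets A and B."""
    if len(subset_a_ids) == 0 or len(subset_b_ids) == 0:
        raise DataContractError("both subsets must be non-empty")
    a = features.loc[list(subset_a_ids)]
    b = features.loc[list(subset_b_ids)]
    out = {}
    for col in features.columns:
        out[col] = float(stats.ks_2samp(a[col], b[col]).statistic)
    return out


def _random_genome(n_var: int, n_rec: int, cap: int, rng: np.random.Generator) -> TwistGenome:
    mask = rng.random(n_var) < 0.5
    while mask.sum() < 2:
        mask[rng.integers(n_var)] = True
    n_a = n_rec // 2 + int(rng.integers(-(cap // 2) - 1, cap // 2 + 2))
    n_a = int(np.clip(n_a, 2, n_rec - 2))
    split = np.zeros(n_rec, dtype=bool)
    split[rng.permutation(n_rec)[:n_a]] = True
    return TwistGenome(mask, split)


def _repair(genome: TwistGenome, cap: int, rng: np.random.Generator) -> TwistGenome:
    mask, split = genome.variable_mask, genome.split_a
    while mask.sum() < 2:
        mask[rng.integers(len(mask))] = True
    n = len(split)
    while abs(int(split.sum()) - (n - int(split.sum()))) > cap:
        n_a = int(split.sum())
        if n_a > n - n_a:  # too many A: flip a random A to B
            idx = rng.choice(np.nonzero(split)[0])
            split[idx] = False
        else:
            idx = rng.choice(np.nonzero(~split)[0])
            split[idx] = True
    return genome


def _crossover(p1: TwistGenome, p2: TwistGenome, rng: np.random.Generator) -> TwistGenome:
    take1_mask = rng.random(len(p1.variable_mask)) < 0.5
    take1_split = rng.random(len(p1.split_a)) < 0.5
    return TwistGenome(
        np.where(take1_mask, p1.variable_mask, p2.variable_mask),
        np.where(take1_split, p1.split_a, p2.split_a),
    )


def _mutate(genome: TwistGenome, rate_mask: float, n_swaps: int,
            rng: np.random.Generator) -> TwistGenome:
    mask = genome.variable_mask.copy()
    flip = rng.random(len(mask)) < rate_mask
    mask[flip] = ~mask[flip]
    split = genome.split_a.copy()
    a_idx = np.nonzero(split)[0]
    b_idx = np.nonzero(~split)[0]
    for _ in range(n_swaps):
        if len(a_idx) and len(b_idx):
            i = rng.choice(a_idx)
            j = rng.choice(b_idx)
            split[i], split[j] = False, True
            a_idx = np.nonzero(split)[0]
            b_idx = np.nonzero(~split)[0]
    return TwistGenome(mask, split)


def run_twist(features: pd.DataFrame, targets, config: TwistConfig) -> TwistResult:
    """Evolve (variable subset, A/B split) to maximise two-run generalisation.

    ``features`` is a records × variables frame (index = record ids);
    reproducible for a fixed ``config.seed``.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    n_rec, n_var = x.shape
    if n_rec < 20:
        raise InvalidConfigError(f"need at least 20 records, got {n_rec}")
    if n_var < 2:
        raise InvalidConfigError(f"need at least 2 variables, got {n_var}")
    if len(y) != n_rec:
        raise DataContractError("targets must match the feature rows")

    rng = np.random.default_rng(config.seed)
    cap = max(1, int(round(config.imbalance_cap_frac * n_rec)))
    rate_mask = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_var
    settings = MlpSettings(
        n_inputs=2,  # replaced per genome
        n_hidden=config.mlp_hidden,
        learning_rate=config.mlp_learning_rate,
        momentum=config.mlp_momentum,
        max_epochs=config.mlp_epochs,
        seed=config.seed % (2**31 - 1),
    )

    cache: dict[bytes, float] = {}
    evaluations = 0

    def fitness(g: TwistGenome) -> float:
        nonlocal evaluations
        k = g.key()
        if k not in cache:
            cache[k] = evaluate_fitness(
                g, x, y, settings, config.parsimony_weight, cap
            )
            evaluations += 1
        return cache[k]

    pop = [_random_genome(n_var, n_rec, cap, rng) for _ in range(config.population_size)]
    scores = [fitness(g) for g in pop]
    history: list[float] = []
    for _ in range(config.generations):
        order = np.argsort(scores)[::-1]
        elite = [pop[i] for i in order[: config.elitism]]
        children: list[TwistGenome] = list(elite)
        while len(children) < config.population_size:
            # tournament selection, k=2
            picks = rng.integers(0, len(pop), size=4)
            p1 = pop[picks[0]] if scores[picks[0]] >= scores[picks[1]] else pop[picks[1]]
            p2 = pop[picks[2]] if scores[picks[2]] >= scores[picks[3]] else pop[picks[3]]
            child = _crossover(p1, p2, rng) if rng.random() < config.crossover_rate \
                else TwistGenome(p1.variable_mask.copy(), p1.split_a.copy())
            child = _mutate(child, rate_mask, n_swaps=1, rng=rng)
            child = _repair(child, cap, rng)
            children.append(child)
        pop = children
        scores = [fitness(g) for g in pop]
        history.append(max(scores))

    best = pop[int(np.argmax(scores))]
    ids = list(features.index)
    a_ids = [ids[i] for i in np.nonzero(best.split_a)[0]]
    b_ids = [ids[i] for i in np.nonzero(~best.split_a)[0]]
    sel = [features.columns[i] for i in np.nonzero(best.variable_mask)[0]]
    return TwistResult(
        selected_variables=list(sel),
        subset_a_ids=a_ids,
        subset_b_ids=b_ids,
        best_fitness_history=history,
        split_similarity=split_similarity(features, a_ids, b_ids),
        best_fitness=float(max(scores)),
        evaluations=evaluations,
    )
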