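import math

import numpy as np
import pytest

from covote.io import ExpressionDataset, GeneList
from covote.preprocess import ConditionMatrix
from covote.synthetic import CorpusParams, simulate_corpus


@pytest.fixture
def toy_cm():
    """Hand-enumerated 2-gene, 3-condition matrix.

    Comparisons (A,B), (A,C), (B,C): both genes jump by +/-2 log2 units in
    (A,B) and (B,C), giving x=3, Q=2 for both genes and N12=2.
    """
    return ConditionMatrix(
        dataset_id="toy",
        genes=["g1", "g2"],
        conditions=["A", "B", "C"],
        values=np.array([[1.0, 3.0, 1.0], [2.0, 4.0, 2.0]]),
        replicate_counts={"A": 1, "B": 1, "C": 1},
    )


@pytest.fixture
def toy_universe():
    return GeneList("universe", ["g1", "g2"])


def random_condition_matrix(rng, n_genes, n_conditions, dataset_id="r"):
    """Small random matrix with occasional missing cells for fuzzing."""
    values = rng.normal(14.0, 1.5, size=(n_genes, n_conditions))
    mask = rng.random(values.shape) < 0.1
    values[mask] = np.nan
    genes = [f"g{i}" for i in range(n_genes)]
    conditions = [f"c{j}" for j in range(n_conditions)]
    return ConditionMatrix(dataset_id, genes, conditions, values,
                           {c: 1 for c in conditions})


def random_corpus(seed, n_genes=8, max_datasets=4):
    rng = np.random.default_rng(seed)
    n_datasets = int(rng.integers(1, max_datasets + 1))
    return [
        random_condition_matrix(rng, n_genes, int(rng.integers(2, 6)), f"d{k}")
        for k in range(n_datasets)
    ]


def oracle_counts(cms, universe, fold_threshold=2.0):
    """Naive triple-loop recount of N, Q, x, independent of build_map."""
    genes = list(universe)
    N = {(a, b): 0 for a in genes for b in genes}
    Q = {g: 0 for g in genes}
    x = 0
    cut = math.log2(fold_threshold)
    for cm in cms:
        for i in range(len(cm.conditions)):
            for j in range(i + 1, len(cm.conditions)):
                x += 1
                calls = {}
                for r, g in enumerate(cm.genes):
                    if g not in Q:
                        continue
                    va, vb = cm.values[r, i], cm.values[r, j]
                    if not (math.isfinite(va) and math.isfinite(vb)):
                        continue
                    d = vb - va
                    calls[g] = 1 if d >= cut else (-1 if d <= -cut else 0)
                for g, c in calls.items():
                    if c != 0:
                        Q[g] += 1
                for a, ca in calls.items():
                    for b, cb in calls.items():
                        if ca != 0 and ca == cb:
                            N[(a, b)] += 1
    return N, Q, x


def binomial_tail_oracle(k, n, p):
    """Exhaustive-enumeration right tail, independent of scipy."""
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * (p ** j) * ((1 - p) ** (n - j))
    return total


@pytest.fixture(scope="session")
def small_module_corpus():
    """One planted module of 10 genes in a 120-gene universe."""
    params = CorpusParams(
        G=120, D=15, conditions_per_dataset=4, replicates_per_condition=2,
        module_sizes=(10,), co_de_prob=0.9, background_de_rate=0.1,
        effect_size_log2=2.0, noise_sd=0.2, missing_rate=0.02, rng_seed=7,
    )
    datasets, truth = simulate_corpus(params)
    return params, datasets, truth
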