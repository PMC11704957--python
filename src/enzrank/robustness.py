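"""Training-data requirements: subsampling curves, CI-width stopping rule,
success rate and skewness diagnostics.

The protocol asks "how many labeled sequences are enough?": for a grid of
training-set sizes, the labeled data are repeatedly subsampled, a regressor
is tuned and fit on each subsample, and its Spearman rank correlation is
measured on one fixed held-out test split. A size is adequate once the 95%
confidence interval of the replicate correlations is narrower than 0.1 (and
stays so at every larger sampled size); the success rate is the fraction of
replicates with rho above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .embedders import EmbeddingMatrix
from .regression import (
    RegressorSpec,
    grid_search_train,
    predict,
    spearman_rho,
)
from .seqio import FitnessDataset

__all__ = [
    "SubsampleCurve",
    "subsample_correlations",
    "ci_width",
    "success_rate",
    "min_adequate_size",
    "fisher_skewness",
    "write_curve_tsv",
]


@dataclass
class SubsampleCurve:
    """Replicate Spearman correlations per training-set size, with the
    derived CI widths and success rates."""

    sizes: list[int]
    correlations: dict[int, list[float]]
    reps: int
    seed: int
    ci_widths: dict[int, float]
    success_rates: dict[int, float]

    def __post_init__(self) -> None:
        if sorted(self.sizes) != self.sizes:
            raise ValueError("sizes must be increasing")
        for s in self.sizes:
            if len(self.correlations[s]) != self.reps:
                raise ValueError(f"size {s}: expected {self.reps} replicates")

    def mean_rho(self, size: int) -> float:
        return float(np.mean(self.correlations[size]))


def ci_width(values: Sequence[float], level: float = 0.95) -> float:
    """Width of the t-distribution confidence interval for the mean:
    ``2 * t_{(1+level)/2, n-1} * sd / sqrt(n)``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if np.ptp(values) == 0:
        return 0.0
    sd = values.std(ddof=1)
    n = len(values)
    t = stats.t.ppf((1 + level) / 2, df=n - 1)
    return float(2 * t * sd / np.sqrt(n))


def success_rate(values: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of values strictly above ``threshold``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise ValueError("need at least one value")
    return float(np.mean(values > threshold))


def subsample_correlations(
    dataset: FitnessDataset,
    embeddings: EmbeddingMatrix,
    sizes: Sequence[int],
    spec: RegressorSpec,
    reps: int = 10,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> SubsampleCurve:
    """Learning-curve experiment with a fixed held-out test split.

    The test split (default 20%) is drawn once from the full dataset before
    any subsampling, so curves at different sizes are comparable. For each
    size ``s`` and replicate ``r``, ``s`` examples are drawn without
    replacement from the remaining pool (seeded by ``(seed, s, r)``), tuned
    and fit via :func:`grid_search_train`, and scored by Spearman rho on the
    fixed test set.
    """
    sizes = sorted(int(s) for s in sizes)
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if min(sizes) < 10:
        raise ValueError("sizes below 10 make cross-validated tuning infeasible")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(2, int(np.floor(n * test_fraction + 0.5)))
    test_idx, pool_idx = perm[:n_test], perm[n_test:]
    if max(sizes) > len(pool_idx):
        raise ValueError(
            f"largest size {max(sizes)} exceeds the {len(pool_idx)}-example pool"
        )
    ids = dataset.ids
    y = dataset.transformed_values()
    X_test = embeddings.rows_for([ids[i] for i in test_idx])
    y_test = y[test_idx]

    correlations: dict[int, list[float]] = {}
    for s in sizes:
        rhos = []
        for r in range(reps):
            sub_rng = np.random.default_rng([seed, s, r])
            chosen = sub_rng.choice(pool_idx, size=s, replace=False)
            model = grid_search_train(
                embeddings.rows_for([ids[i] for i in chosen]),
                y[chosen],
                spec,
                train_ids=[ids[i] for i in chosen],
                layer=embeddings.layer,
                transform=dataset.transform,
            )
            rhos.append(spearman_rho(predict(model, X_test), y_test))
        correlations[s] = rhos
    return SubsampleCurve(
        sizes=list(sizes),
        correlations=correlations,
        reps=reps,
        seed=seed,
        ci_widths={s: ci_width(correlations[s]) for s in sizes},
        success_rates={s: success_rate(correlations[s]) for s in sizes},
    )


def min_adequate_size(
    curve: SubsampleCurve, max_ci_width: float = 0.1
) -> int | None:
    """Smallest size whose CI width is below ``max_ci_width`` AND stays
    below it at every larger sampled size; ``None`` if no size qualifies.

    The stability requirement guards against noise-induced early crossings.
    """
    adequate = None
    for s in reversed(curve.sizes):
        if curve.ci_widths[s] < max_ci_width:
            adequate = s
        else:
            break
    return adequate


def fisher_skewness(values: Sequence[float]) -> float:
    """Fisher's moment coefficient of skewness, unadjusted:
    ``g1 = m3 / m2^(3/2)`` with central moments ``m_k``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("undefined skewness: zero variance")
    return float(stats.skew(values, bias=True))


def write_curve_tsv(curve: SubsampleCurve, path: str | Path) -> None:
    """Serialize a curve: per-replicate rows plus a summary block."""
    with open(path, "w") as fh:
        fh.write(f"# seed={curve.seed}\treps={curve.reps}\n")
        fh.write("size\trep\trho\n")
        for s in curve.sizes:
            for r, rho in enumerate(curve.correlations[s]):
                fh.write(f"{s}\t{r}\t{rho:.6f}\n")
        fh.write("size\tmean_rho\tci_width\tsuccess_rate\n")
        for s in curve.sizes:
            fh.write(
                f"{s}\t{curve.mean_rho(s):.6f}\t{curve.ci_widths[s]:.6f}"
                f"\t{curve.success_rates[s]:.6f}\n"
            )
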