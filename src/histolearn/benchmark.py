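"""Label-efficiency benchmark: uncertainty sampling vs random sampling.

The central promise of active learning is that steering the annotator
toward low-confidence objects reaches a given accuracy with fewer labels
than labeling randomly chosen objects. This module runs paired simulations
on the synthetic benchmark: for each seed, both strategies start from the
same 8 seed labels and the loop runs until the held-out AUC reaches a
target, recording how many labels each needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .active_learner import ForestParams, LoopHistory, run_learning_loop
from .synthetic_data import SimConfig, make_seed_labels, simulate_benchmark, truth_oracle

__all__ = ["EfficiencyResult", "labels_to_target", "run_efficiency_comparison"]


def labels_to_target(history: LoopHistory, auc_target: float) -> int | None:
    """Training-set size at which the held-out AUC first reached the target."""
    for rec in history.records:
        if rec["auc"] >= auc_target:
            return rec["train_size"]
    return None


@dataclass
class EfficiencyResult:
    """Paired per-seed label counts needed to reach the AUC target."""

    auc_target: float
    censor_at: int  # label budget; unreached targets count as censor_at
    labels_uncertainty: list[int] = field(default_factory=list)
    labels_random: list[int] = field(default_factory=list)
    initial_auc: list[float] = field(default_factory=list)
    final_auc: list[float] = field(default_factory=list)

    @property
    def median_uncertainty(self) -> float:
        return float(np.median(self.labels_uncertainty))

    @property
    def median_random(self) -> float:
        return float(np.median(self.labels_random))

    def sign_test_pvalue(self) -> float:
        """One-sided sign test that uncertainty needs fewer labels than random."""
        from scipy.stats import binomtest

        u = np.array(self.labels_uncertainty)
        r = np.array(self.labels_random)
        informative = u != r
        wins = int(np.sum(u[informative] < r[informative]))
        n = int(informative.sum())
        if n == 0:
            return 1.0
        return float(binomtest(wins, n, 0.5, alternative="greater").pvalue)


def run_efficiency_comparison(
    config: SimConfig | None = None,
    n_seeds: int = 10,
    auc_target: float = 0.95,
    k: int = 8,
    max_iterations: int = 40,
    seed_offset: int = 0,
) -> EfficiencyResult:
    """Paired uncertainty-vs-random runs over ``n_seeds`` benchmark replicates.

    Each replicate regenerates the benchmark with its own seed, draws the
    same 8 seed labels for both strategies, and runs the loop until the
    held-out AUC reaches ``auc_target`` or the iteration cap. A run that
    never reaches the target is censored at the full label budget.
    """
    base = config or SimConfig()
    n_seed_labels = 8
    censor_at = n_seed_labels + max_iterations * k + 1
    result = EfficiencyResult(auc_target=auc_target, censor_at=censor_at)
    for i in range(n_seeds):
        seed = seed_offset + i
        cfg = base.with_seed(seed)
        _slides, store, truth, validation = simulate_benchmark(cfg)
        seed_labels = make_seed_labels(truth, per_class=n_seed_labels // 2, seed=seed)
        oracle = truth_oracle(truth)
        candidates = set(truth.entries)
        histories = {}
        for strategy in ("uncertainty", "random"):
            _m, _l, hist = run_learning_loop(
                store,
                seed_labels,
                oracle,
                params=ForestParams(),
                k=k,
                max_iterations=max_iterations,
                auc_target=auc_target,
                validation=validation,
                strategy=strategy,
                candidates=candidates,
                master_seed=seed,
            )
            histories[strategy] = hist
            reached = labels_to_target(hist, auc_target)
            count = censor_at if reached is None else reached
            if strategy == "uncertainty":
                result.labels_uncertainty.append(count)
            else:
                result.labels_random.append(count)
        result.initial_auc.append(histories["uncertainty"].records[0]["auc"])
        result.final_auc.append(histories["uncertainty"].final_auc)
    return result
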