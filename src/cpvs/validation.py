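"""Empirical validity / efficiency checks for the conformal predictor.

Runs the mondrian ICP on exchangeable synthetic data (two Gaussian classes)
across seeds and significance levels, and tabulates the true-label
exclusion rate against its guarantee: at significance epsilon the true
label may be excluded at most an epsilon fraction of the time on average,
per class. The comparison bound adds three binomial standard errors,
``epsilon + 3 * sqrt(epsilon * (1 - epsilon) / n)``, to account for the
finite test sample.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import cp
from .synthetic import generate_cp_benchmark


def validity_bound(epsilon: float, n: int) -> float:
    """epsilon plus three binomial standard errors at sample size n."""
    return epsilon + 3.0 * np.sqrt(epsilon * (1.0 - epsilon) / n)


def validity_table(epsilons: Sequence[float] = (0.1, 0.2),
                   seeds: Iterable[int] = range(1, 21),
                   n_train: int = 2000,
                   n_cal: int = 500,
                   n_test: int = 2000,
                   dim: int = 10,
                   separation: float = 1.0,
                   class_balance: float = 0.5,
                   max_opt_iterations: int = cp.DEFAULT_MAX_OPT_ITERATIONS,
                   ) -> pd.DataFrame:
    """Mean exclusion rates and efficiency per epsilon, averaged over seeds.

    The scorer and calibration are shared across the epsilon grid within a
    seed (p-values do not depend on epsilon), so the table is cheap to
    extend to more significance levels.

    Returns one row per epsilon with columns: ``epsilon``, ``error_overall``,
    ``error_class0``, ``error_class1``, ``efficiency``, ``n_test``,
    ``n_seeds``, ``bound_overall``, ``bound_class0``, ``bound_class1``.
    """
    seeds = list(seeds)
    records: dict[float, list[dict]] = {e: [] for e in epsilons}
    for seed in seeds:
        bench = generate_cp_benchmark(
            n_train=n_train, n_cal=n_cal, n_test=n_test, dim=dim,
            class_balance=class_balance, separation=separation, seed=seed)
        scorer = cp.train_underlying(bench.X_train, bench.y_train,
                                     max_opt_iterations=max_opt_iterations)
        icp = cp.ICPClassifier.from_calibration(
            scorer, bench.X_cal, bench.y_cal, epsilon=min(epsilons))
        p0, p1 = icp.p_values(bench.X_test)
        y = bench.y_test
        p_true = np.where(y == 1, p1, p0)
        for eps in epsilons:
            excluded = p_true <= eps
            in0, in1 = p0 > eps, p1 > eps
            records[eps].append({
                "error_overall": float(excluded.mean()),
                "error_class0": float(excluded[y == 0].mean()),
                "error_class1": float(excluded[y == 1].mean()),
                "efficiency": float((in0 ^ in1).mean()),
                "n_class0": int((y == 0).sum()),
                "n_class1": int((y == 1).sum()),
            })

    rows = []
    for eps in epsilons:
        df = pd.DataFrame(records[eps])
        n0 = int(df["n_class0"].mean())
        n1 = int(df["n_class1"].mean())
        rows.append({
            "epsilon": eps,
            "error_overall": df["error_overall"].mean(),
            "error_class0": df["error_class0"].mean(),
            "error_class1": df["error_class1"].mean(),
            "efficiency": df["efficiency"].mean(),
            "n_test": n_test,
            "n_seeds": len(seeds),
            "bound_overall": validity_bound(eps, n_test),
            "bound_class0": validity_bound(eps, n0),
            "bound_class1": validity_bound(eps, n1),
        })
    return pd.DataFrame(rows)
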