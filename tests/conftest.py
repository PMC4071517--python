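"""Shared fixtures: tiny hand-built datasets and an independent
brute-force model-averaging oracle (statsmodels-based, coded separately
from the package's linear algebra)."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from kinscape import GenotypeMatrix, SampleTable


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """4 individuals x 3 polymorphic loci, no missing data."""
    return GenotypeMatrix(
        ["a", "b", "c", "d"],
        ["L1", "L2", "L3"],
        np.array(
            [[1, 1, 0],
             [1, 1, 0],
             [0, 0, 1],
             [0, 1, 1]], dtype=float),
    )


@pytest.fixture
def toy_samples() -> SampleTable:
    """4 individuals with coordinates, 2 environmental variables, 2 associations."""
    return SampleTable(
        pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "lon": [0.0, 0.01, 0.0, 0.02],
                "lat": [0.0, 0.0, 0.01, 0.02],
                "association": ["wet", "wet", "dry", "dry"],
                "altitude": [100.0, 350.0, 200.0, 50.0],
                "soil_ph": [5.0, 6.0, 5.5, 7.0],
            }
        )
    )


def brute_force_model_average(
    y: np.ndarray, predictors: dict[str, np.ndarray]
) -> dict:
    """Independent enumeration of all submodels via statsmodels OLS.

    Returns AICc, Akaike weights, and conditionally averaged estimates
    with Burnham & Anderson unconditional SEs, computed from scratch.
    """
    import statsmodels.api as sm

    names = list(predictors)
    m = len(y)
    subsets, results, aiccs = [], [], []
    for size in range(len(names) + 1):
        for sub in combinations(names, size):
            if sub:
                X = sm.add_constant(np.column_stack([predictors[s] for s in sub]))
            else:
                X = np.ones((m, 1))
            res = sm.OLS(y, X).fit()
            k = len(sub) + 2  # intercept + slopes + residual variance
            aicc = -2.0 * res.llf + 2 * k + 2 * k * (k + 1) / (m - k - 1)
            subsets.append(sub)
            results.append(res)
            aiccs.append(aicc)
    aiccs = np.array(aiccs)
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()

    averaged, ses = {}, {}
    for t in names:
        contains = [g for g, sub in enumerate(subsets) if t in sub]
        wg = w[contains] / w[contains].sum()
        est = np.array(
            [results[g].params[list(subsets[g]).index(t) + 1] for g in contains]
        )
        var = np.array(
            [results[g].bse[list(subsets[g]).index(t) + 1] ** 2 for g in contains]
        )
        theta = float(wg @ est)
        averaged[t] = theta
        ses[t] = float(wg @ np.sqrt(var + (est - theta) ** 2))
    return {
        "subsets": subsets,
        "aicc": aiccs,
        "weights": w,
        "estimates": averaged,
        "se": ses,
    }


def random_regression_problem(rng: np.random.Generator, p: int, m: int):
    """A random response + p correlated predictor vectors of length m."""
    base = rng.standard_normal((m, p))
    mix = rng.uniform(-0.5, 0.5, size=(p, p))
    np.fill_diagonal(mix, 1.0)
    X = base @ mix
    beta = rng.uniform(-1, 1, size=p)
    y = X @ beta + rng.standard_normal(m)
    preds = {f"x{j}": X[:, j] for j in range(p)}
    return y, preds
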