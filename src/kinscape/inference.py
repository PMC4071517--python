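"""Permutation null, z-scores, p-values and FDR control.

Pairwise observations in a matrix regression are not independent, so the
nominal confidence intervals from model averaging are not by themselves
trustworthy. Significance is therefore established twice: the CI must
exclude zero, AND the model-averaged coefficient must be extreme against
a Mantel-style permutation null, built by jointly permuting the rows and
columns of the kinship matrix (relabelling the individuals) while the
predictor matrices stay fixed. Because a label permutation only reorders
the off-diagonal multiset, the standardized response is permutation
invariant up to order and no re-standardization is needed.

For each term the observed estimate is compared with B permuted
estimates: z = (obs - mean_null)/sd_null, a normal-theory p from z, and
the empirical two-sided p = (1 + #{|null| >= |obs|})/(1 + B), which can
never be exactly zero. Across terms, p-values are adjusted with the
Benjamini-Hochberg step-up procedure at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError
from .kinship import PairwiseMatrix
from .model_averaging import AveragedEffect, SubsetEngine, average_effects, unfold

__all__ = [
    "PermutationResult",
    "permute_response",
    "permutation_test",
    "fdr_adjust",
    "attach_inference",
]

logger = logging.getLogger("kinscape")


@dataclass
class PermutationResult:
    """Observed vs permuted model-averaged estimates for every term."""

    terms: list[str]
    observed: np.ndarray           #: (p,) observed averaged estimates
    permuted: np.ndarray           #: (p, B) null averaged estimates
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray                  #: NaN where sd_null == 0
    p_normal: np.ndarray
    p_empirical: np.ndarray
    seed: int

    @property
    def n_permutations(self) -> int:
        return self.permuted.shape[1]


def permute_response(kinship: PairwiseMatrix, seed) -> PairwiseMatrix:
    """Jointly permute rows and columns by one random relabelling.

    ``seed`` may be an int or a numpy Generator. The matrix's internal
    structure (the off-diagonal multiset) is preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(kinship.n)
    return PairwiseMatrix(
        list(kinship.individual_ids),
        kinship.values[np.ix_(perm, perm)],
        kind=kinship.kind,
    )


def _permutation_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def permutation_test(
    response: PairwiseMatrix | np.ndarray,
    predictors: dict[str, np.ndarray],
    B: int = 1000,
    seed: int | None = None,
    averaging: str = "conditional",
) -> PermutationResult:
    """Permutation null distribution of the model-averaged coefficients.

    ``response`` is the (standardized) kinship matrix, or an already
    unfolded vector together with the matrix dimension implied by its
    length; predictors are unfolded vectors sharing the pair order. For
    each of B label permutations the full all-subsets averaging pipeline
    is re-run on the permuted response with unchanged predictors.

    A single seed governs the whole permutation stream, so identical
    seeds give identical results.
    """
    if B < 99:
        raise ValidationError("B must be >= 99 for a usable empirical p")
    if isinstance(response, PairwiseMatrix):
        K = response.values
        n = response.n
        y = unfold(response)
    else:
        y = np.asarray(response, dtype=float)
        n = int((1 + np.sqrt(1 + 8 * len(y))) / 2)
        from .model_averaging import refold

        K = refold(y, [str(i) for i in range(n)], kind="kinship").values
    engine = SubsetEngine(predictors)
    if averaging != "conditional":
        raise ValidationError("permutation fast path implements conditional averaging")
    observed = engine.averaged_estimates_many(y[:, None])[:, 0]

    rng = np.random.default_rng(seed)
    il, jl = _permutation_index(n)
    Y = np.empty((len(y), B))
    for b in range(B):
        perm = rng.permutation(n)
        Y[:, b] = K[perm[il], perm[jl]]
    permuted = engine.averaged_estimates_many(Y)       # (p, B)

    null_mean = permuted.mean(axis=1)
    null_sd = permuted.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    degenerate = null_sd == 0
    if degenerate.any():
        bad = [engine.names[i] for i in np.flatnonzero(degenerate)]
        logger.warning(
            "null sd is zero for %s; z undefined, using empirical p only", bad
        )
        z[degenerate] = np.nan
    p_normal = 2.0 * stats.norm.sf(np.abs(z))
    p_empirical = (
        1.0 + (np.abs(permuted) >= np.abs(observed)[:, None]).sum(axis=1)
    ) / (1.0 + B)
    return PermutationResult(
        terms=list(engine.names),
        observed=observed,
        permuted=permuted,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_normal=p_normal,
        p_empirical=p_empirical,
        seed=-1 if seed is None else int(seed),
    )


def fdr_adjust(
    pvalues, method: str = "BH", level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg q-values and discovery flags at the given level."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if method != "BH":
        raise ValidationError(f"unsupported FDR method {method!r}")
    _, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, q <= level


def attach_inference(
    effects: list[AveragedEffect],
    perm: PermutationResult,
    level: float = 0.05,
    p_source: str = "empirical",
) -> list[AveragedEffect]:
    """Join permutation statistics onto the averaged effects (in place).

    Final significance is the dual criterion: the 95% CI excludes zero
    AND the chosen permutation p-value survives FDR control at ``level``.
    ``p_source`` selects the empirical permutation p (default) or the
    normal-theory p from z.
    """
    if p_source not in ("empirical", "normal"):
        raise ValidationError(f"unknown p_source {p_source!r}")
    order = {t: i for i, t in enumerate(perm.terms)}
    for e in effects:
        if e.term not in order:
            raise ValidationError(f"no permutation result for term {e.term!r}")
    p = np.array(
        [
            perm.p_empirical[order[e.term]]
            if p_source == "empirical"
            else perm.p_normal[order[e.term]]
            for e in effects
        ]
    )
    q, disc = fdr_adjust(p, level=level)
    for e, qi, di in zip(effects, q, disc):
        i = order[e.term]
        e.z = float(perm.z[i])
        e.p_normal = float(perm.p_normal[i])
        e.p_empirical = float(perm.p_empirical[i])
        e.q = float(qi)
        e.significant_final = bool(e.significant_ci and di)
        if not e.significant_final:
            e.direction = "none"
        else:
            e.direction = "isolation" if e.estimate < 0 else "counter-gradient"
    return effects
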