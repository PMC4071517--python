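"""All-subsets multiple-matrix regression with AICc model averaging.

The response (unfolded kinship) is regressed on every subset of the
candidate predictor vectors (2^p ordinary-least-squares fits including
the intercept-only model). Each submodel g receives an Akaike weight

    w_g = exp(-Delta_g / 2) / sum_h exp(-Delta_h / 2),
    Delta_g = AICc_g - min_h AICc_h,

with the small-sample criterion AICc = -2 logLik + 2k + 2k(k+1)/(m-k-1),
Gaussian logLik = -m/2 (ln(2 pi RSS/m) + 1), and k counting the
intercept, the slopes and the residual variance.

Per-term estimates are then model-averaged. The default is conditional
("natural") averaging over the submodels in which the term appears, with
weights renormalized to that subset; full-model (shrinkage) averaging is
available. The unconditional standard error follows Burnham & Anderson's
weighted-sum-of-roots form

    SE_j = sum_g w'_g sqrt( var(b_jg) + (b_jg - bbar_j)^2 ),

which folds between-model spread into the sampling variance; the revised
square-root-of-weighted-sum variant is available behind a flag. 95%
confidence intervals use the normal multiplier 1.96 (pair counts are in
the hundreds to thousands, so the t correction is negligible) and a term
is CI-significant when its interval excludes zero: negative significant
effects are classified "isolation", positive ones "counter-gradient".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_formats import KinscapeError, ValidationError
from .kinship import PairwiseMatrix

__all__ = [
    "SubmodelFit",
    "AveragedEffect",
    "unfold",
    "refold",
    "fit_all_subsets",
    "average_effects",
    "SubsetEngine",
    "CI_MULTIPLIER",
]

CI_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# matrix unfolding
# ---------------------------------------------------------------------------

def unfold(matrix: PairwiseMatrix, atol: float = 1e-8) -> np.ndarray:
    """Lower triangle (i > j) of a symmetric matrix, row-major.

    All matrices in a run share the individual order, so all unfold in the
    same pair order; length is n(n-1)/2.
    """
    v = matrix.values
    off = ~np.eye(matrix.n, dtype=bool)
    if not np.allclose(v[off], v.T[off], atol=atol, rtol=0, equal_nan=True):
        raise ValidationError("matrix asymmetric beyond tolerance; cannot unfold")
    i, j = np.tril_indices(matrix.n, k=-1)
    return v[i, j].copy()


def refold(vector: np.ndarray, ids: list[str], kind: str = "distance") -> PairwiseMatrix:
    """Inverse of :func:`unfold` (diagonal set to 0, or NaN for kinship)."""
    m = len(vector)
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n * (n - 1) // 2 != m:
        raise ValidationError(f"vector length {m} is not a triangular number")
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    out[i, j] = vector
    out[j, i] = vector
    if kind == "kinship":
        np.fill_diagonal(out, np.nan)
    return PairwiseMatrix(ids, out, kind=kind)


# ---------------------------------------------------------------------------
# submodel fits
# ---------------------------------------------------------------------------

@dataclass
class SubmodelFit:
    """One OLS fit of the response on a subset of predictor terms."""

    terms: tuple[str, ...]
    coef: dict[str, float]
    coef_var: dict[str, float]
    rss: float
    loglik: float
    k: int
    aicc: float
    weight: float = float("nan")


@dataclass
class AveragedEffect:
    """Model-averaged effect of one predictor on kinship.

    ``direction`` is "isolation" for a significant negative effect
    (relatedness declines with the distance measure), "counter-gradient"
    for a significant positive effect, else "none". The permutation
    fields (z, p values, q, significant_final) are attached by
    :mod:`kinscape.inference`.
    """

    term: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    significant_ci: bool
    direction: str
    z: float = float("nan")
    p_normal: float = float("nan")
    p_empirical: float = float("nan")
    q: float = float("nan")
    significant_final: bool | None = None

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.estimate <= self.ci_hi):
            raise KinscapeError("CI does not bracket the averaged estimate")


class SubsetEngine:
    """Precomputed linear algebra for all 2^p submodels of a fixed design.

    The Gram matrix of the interceptful design is factorized once per
    subset, so fitting the same submodels to many response vectors (the
    permutation null) costs only small matrix-vector products.
    """

    def __init__(self, predictors: dict[str, np.ndarray]):
        self.names = list(predictors)
        p = len(self.names)
        if p == 0:
            raise ValidationError("need at least one predictor")
        cols = [np.asarray(predictors[n], dtype=float) for n in self.names]
        m = len(cols[0])
        for n, c in zip(self.names, cols):
            if c.shape != (m,):
                raise ValidationError(f"predictor {n!r} has mismatched length")
        if m < p + 3:
            raise ValidationError(
                f"{m} pairs is too few for {p} predictors (need >= p + 3)"
            )
        k_max = p + 2
        if m - k_max - 1 <= 0:
            raise ValidationError("sample size too small for AICc of the full model")
        self.m = m
        self.Z = np.column_stack([np.ones(m)] + cols)   # intercept first
        self.G = self.Z.T @ self.Z
        self.subsets: list[tuple[int, ...]] = [
            s for size in range(p + 1) for s in combinations(range(p), size)
        ]
        self._ginv: list[np.ndarray] = []
        for s in self.subsets:
            idx = (0,) + tuple(i + 1 for i in s)
            G_s = self.G[np.ix_(idx, idx)]
            try:
                ginv = np.linalg.inv(G_s)
            except np.linalg.LinAlgError as exc:
                bad = [self.names[i] for i in s]
                raise KinscapeError(
                    f"collinear design within submodel {bad} (run the VIF screen)"
                ) from exc
            if np.linalg.cond(G_s) > 1e10:
                bad = [self.names[i] for i in s]
                raise KinscapeError(
                    f"near-singular design within submodel {bad} (run the VIF screen)"
                )
            self._ginv.append(ginv)

    # -- single response -> full SubmodelFit objects ------------------------

    def fit(self, response: np.ndarray) -> list[SubmodelFit]:
        y = np.asarray(response, dtype=float)
        if y.shape != (self.m,):
            raise ValidationError("response length does not match design")
        zty = self.Z.T @ y
        yty = float(y @ y)
        fits: list[SubmodelFit] = []
        m = self.m
        for s, ginv in zip(self.subsets, self._ginv):
            idx = (0,) + tuple(i + 1 for i in s)
            beta = ginv @ zty[list(idx)]
            rss = max(yty - float(beta @ zty[list(idx)]), 1e-300)
            n_par = len(idx)                       # intercept + slopes
            sigma2 = rss / (m - n_par)             # conventional OLS variance
            var = sigma2 * np.diag(ginv)
            loglik = -m / 2.0 * (np.log(2.0 * np.pi * rss / m) + 1.0)
            k = n_par + 1                          # + residual variance
            aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (m - k - 1)
            fits.append(
                SubmodelFit(
                    terms=tuple(self.names[i] for i in s),
                    coef={self.names[i]: float(b) for i, b in zip(s, beta[1:])},
                    coef_var={self.names[i]: float(v) for i, v in zip(s, var[1:])},
                    rss=rss,
                    loglik=loglik,
                    k=k,
                    aicc=aicc,
                )
            )
        _set_weights(fits)
        return fits

    # -- many responses -> averaged estimates only (permutation fast path) --

    def averaged_estimates_many(self, Y: np.ndarray) -> np.ndarray:
        """Conditional model-averaged estimates for each response column.

        ``Y`` is (m, B); returns a (p, B) array of averaged coefficients,
        term order matching ``self.names``. Mirrors ``fit`` + conditional
        ``average_effects`` exactly, vectorized over columns.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        m, B = Y.shape
        if m != self.m:
            raise ValidationError("response length does not match design")
        ZtY = self.Z.T @ Y                          # (p+1, B)
        yty = (Y * Y).sum(axis=0)                   # (B,)
        n_sub = len(self.subsets)
        p = len(self.names)
        aicc = np.empty((n_sub, B))
        coefs = np.zeros((n_sub, p, B))             # slope estimates, 0 if absent
        member = np.zeros((n_sub, p), dtype=bool)
        for g, (s, ginv) in enumerate(zip(self.subsets, self._ginv)):
            idx = [0] + [i + 1 for i in s]
            beta = ginv @ ZtY[idx]                  # (k_s, B)
            rss = np.maximum(yty - (beta * ZtY[idx]).sum(axis=0), 1e-300)
            loglik = -m / 2.0 * (np.log(2.0 * np.pi * rss / m) + 1.0)
            k = len(idx) + 1
            aicc[g] = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (m - k - 1)
            for row, i in enumerate(s):
                coefs[g, i] = beta[row + 1]
                member[g, i] = True
        delta = aicc - aicc.min(axis=0, keepdims=True)
        w = np.exp(-delta / 2.0)
        w /= w.sum(axis=0, keepdims=True)           # (n_sub, B)
        out = np.empty((p, B))
        for i in range(p):
            wg = w[member[:, i]]                    # (n_i, B)
            wg = wg / wg.sum(axis=0, keepdims=True)
            out[i] = (wg * coefs[member[:, i], i]).sum(axis=0)
        return out


def _set_weights(fits: list[SubmodelFit]) -> None:
    aicc = np.array([f.aicc for f in fits])
    if not np.isfinite(aicc).all():
        raise KinscapeError("non-finite AICc in candidate set")
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)


def fit_all_subsets(
    response: np.ndarray, predictors: dict[str, np.ndarray]
) -> list[SubmodelFit]:
    """Fit all 2^p submodels (including intercept-only) and weight by AICc."""
    return SubsetEngine(predictors).fit(response)


def average_effects(
    fits: list[SubmodelFit],
    method: str = "conditional",
    se_form: str = "sum_of_roots",
) -> list[AveragedEffect]:
    """Model-averaged coefficient, unconditional SE, CI and classification.

    ``method="conditional"`` (default) averages each term over the
    submodels containing it with renormalized weights; ``method="full"``
    averages over all submodels treating the coefficient as 0 (variance 0)
    where the term is absent, shrinking weakly supported effects.
    ``se_form`` chooses Burnham & Anderson's weighted-sum-of-roots
    (default) or the revised ``"sqrt_of_sum"`` variant.
    """
    if method not in ("conditional", "full"):
        raise ValidationError(f"unknown averaging method {method!r}")
    if se_form not in ("sum_of_roots", "sqrt_of_sum"):
        raise ValidationError(f"unknown SE form {se_form!r}")
    terms: list[str] = []
    for f in fits:
        for t in f.terms:
            if t not in terms:
                terms.append(t)
    effects: list[AveragedEffect] = []
    for t in terms:
        if method == "conditional":
            sub = [f for f in fits if t in f.terms]
            if not sub:
                raise KinscapeError(f"term {t!r} appears in no submodel")
            w = np.array([f.weight for f in sub])
            w = w / w.sum()
            b = np.array([f.coef[t] for f in sub])
            v = np.array([f.coef_var[t] for f in sub])
        else:
            w = np.array([f.weight for f in fits])
            b = np.array([f.coef.get(t, 0.0) for f in fits])
            v = np.array([f.coef_var.get(t, 0.0) for f in fits])
        est = float(w @ b)
        if se_form == "sum_of_roots":
            se = float(w @ np.sqrt(v + (b - est) ** 2))
        else:
            se = float(np.sqrt(w @ (v + (b - est) ** 2)))
        lo, hi = est - CI_MULTIPLIER * se, est + CI_MULTIPLIER * se
        sig = bool(lo > 0 or hi < 0)
        direction = "none"
        if sig:
            direction = "isolation" if est < 0 else "counter-gradient"
        effects.append(
            AveragedEffect(
                term=t, estimate=est, se=se, ci_lo=lo, ci_hi=hi,
                significant_ci=sig, direction=direction,
            )
        )
    return effects
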