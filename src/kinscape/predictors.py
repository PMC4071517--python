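"""Explanatory distance matrices and collinearity screening.

Builds the three classes of predictors regressed against kinship:

* **geography** — great-circle distance between sampling positions
  (isolation by distance, IBD);
* **environment** — per-variable absolute differences, or a single
  combined matrix of Euclidean distances between principal-component
  scores of the standardized environmental variables (isolation by
  environment, IBE);
* **community** — Jaccard dissimilarity between the species sets of the
  individuals' vegetation associations (isolation by community, IBC).

Also provides the aspect -> northeasterly wind exposure transform,
standardization of unfolded pairwise vectors, and iterative removal of
predictors with variance inflation factors above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AssociationLookup, SampleTable, ValidationError
from .kinship import PairwiseMatrix
from .model_averaging import unfold

__all__ = [
    "PredictorSet",
    "geographic_distances",
    "wind_exposure",
    "per_variable_distances",
    "combined_environment_distance",
    "community_distance",
    "standardize_predictors",
    "vif_screen",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class PredictorSet:
    """Named, ordered collection of predictor matrices over identical ids."""

    matrices: dict[str, PairwiseMatrix]
    standardized: bool = False
    #: standardization parameters per name (mean, sd on the unfolded scale)
    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: names removed by the VIF screen, with the VIF at removal
    vif_removed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.matrices)
        if len(set(names)) != len(names):
            raise ValidationError("duplicate predictor names")
        ids = None
        for name, m in self.matrices.items():
            if ids is None:
                ids = m.individual_ids
            elif m.individual_ids != ids:
                raise ValidationError(
                    f"predictor {name!r} has a different individual order"
                )

    @property
    def names(self) -> list[str]:
        return list(self.matrices)

    @property
    def individual_ids(self) -> list[str]:
        return next(iter(self.matrices.values())).individual_ids

    def unfolded(self) -> dict[str, np.ndarray]:
        return {name: unfold(m) for name, m in self.matrices.items()}


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def geographic_distances(
    samples: SampleTable, method: str = "haversine"
) -> PairwiseMatrix:
    """Pairwise geographic distance in metres from decimal-degree coordinates.

    ``method="haversine"`` (default) uses the great-circle distance on a
    sphere of radius 6,371,000 m; ``method="euclidean"`` treats degree
    offsets as planar after scaling longitude by cos(mean latitude) —
    at within-island extents the two agree to well under 0.1%.
    """
    lon = samples.data["lon"].to_numpy(dtype=float)
    lat = samples.data["lat"].to_numpy(dtype=float)
    if method == "haversine":
        d = _haversine_matrix(lon, lat)
    elif method == "euclidean":
        m_per_deg = EARTH_RADIUS_M * np.pi / 180.0
        x = lon * m_per_deg * np.cos(np.radians(lat.mean()))
        y = lat * m_per_deg
        d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    else:
        raise ValidationError(f"unknown distance method {method!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(samples.ids, d, kind="distance")


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def wind_exposure(aspect_degrees):
    """Convert slope aspect to northeasterly wind exposure in [0, 180].

    Exposure is 180 minus the angular distance between the aspect and 45
    degrees (northeast), so a southwest-facing slope (225) scores 0 and a
    northeast-facing slope (45) scores 180.
    """
    a = np.asarray(aspect_degrees, dtype=float)
    if ((a < 0) | (a >= 360)).any():
        raise ValidationError("aspect must lie in [0, 360)")
    exposure = 180.0 - np.abs(((a - 45.0 + 180.0) % 360.0) - 180.0)
    return exposure if exposure.ndim else float(exposure)


def per_variable_distances(
    samples: SampleTable, variables: list[str] | None = None
) -> PredictorSet:
    """One |v_i - v_j| distance matrix per environmental variable."""
    variables = list(variables) if variables is not None else samples.env_names
    env = samples.env
    matrices: dict[str, PairwiseMatrix] = {}
    for var in variables:
        if var not in env.columns:
            raise ValidationError(f"environmental variable {var!r} not in sample table")
        v = env[var].to_numpy(dtype=float)
        if np.isnan(v).any():
            ind = samples.ids[int(np.flatnonzero(np.isnan(v))[0])]
            raise ValidationError(f"missing value of {var!r} for individual {ind!r}")
        d = np.abs(v[:, None] - v[None, :])
        matrices[var] = PairwiseMatrix(samples.ids, d, kind="distance")
    return PredictorSet(matrices)


def _standardize_columns(table: np.ndarray) -> np.ndarray:
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance environmental variable; cannot scale")
    return (table - mu) / sd


def combined_environment_distance(
    samples: SampleTable,
    variables: list[str] | None = None,
    n_components: int | None = None,
) -> PairwiseMatrix:
    """Euclidean distance between principal-component scores of the environment.

    Variables are centred and scaled to unit variance before rotation. With
    all components retained (the default) the rotation is an isometry and
    the result equals Euclidean distance on the standardized table directly;
    ``n_components`` truncates to the leading components if set.
    """
    variables = list(variables) if variables is not None else samples.env_names
    if len(variables) < 2:
        raise ValidationError("combined environmental distance needs >= 2 variables")
    table = samples.env[variables].to_numpy(dtype=float)
    if np.isnan(table).any():
        raise ValidationError("missing environmental values")
    z = _standardize_columns(table)
    # PCA by SVD of the centred-scaled table; scores = U S
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    if n_components is not None:
        scores = scores[:, :n_components]
    diff = scores[:, None, :] - scores[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(samples.ids, d, kind="distance")


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------

def community_distance(
    samples: SampleTable, lookup: AssociationLookup
) -> PairwiseMatrix:
    """Jaccard dissimilarity between individuals' association species sets."""
    lookup.validate_covers(samples)
    assoc = list(samples.association)
    labels = sorted(set(assoc))
    # dissimilarity between association labels, then broadcast to individuals
    dd = {}
    for a in labels:
        for b in labels:
            sa, sb = lookup[a], lookup[b]
            dd[(a, b)] = 1.0 - len(sa & sb) / len(sa | sb)
    n = len(assoc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d[i, j] = d[j, i] = dd[(assoc[i], assoc[j])]
    return PairwiseMatrix(samples.ids, d, kind="dissimilarity")


# ---------------------------------------------------------------------------
# standardization and collinearity screening
# ---------------------------------------------------------------------------

def standardize_predictors(
    predictors: PredictorSet, response: PairwiseMatrix
) -> tuple[dict[str, np.ndarray], np.ndarray, PredictorSet]:
    """Unfold all matrices and scale each vector to mean 0, sd 1.

    Returns the standardized predictor vectors, the standardized response
    vector, and a copy of the PredictorSet carrying the (mean, sd)
    back-transformation parameters. Standardizing the response alongside
    the predictors makes effect sizes dimensionless and comparable across
    runs and species.
    """
    if predictors.individual_ids != response.individual_ids:
        raise ValidationError("response and predictors have different individuals")
    params: dict[str, tuple[float, float]] = {}
    vectors: dict[str, np.ndarray] = {}
    for name, vec in predictors.unfolded().items():
        mu, sd = float(vec.mean()), float(vec.std(ddof=1))
        if sd == 0:
            raise ValidationError(f"predictor {name!r} has zero variance")
        vectors[name] = (vec - mu) / sd
        params[name] = (mu, sd)
    y = unfold(response)
    mu_y, sd_y = float(np.nanmean(y)), float(np.nanstd(y, ddof=1))
    if sd_y == 0:
        raise ValidationError("response has zero variance")
    y = (y - mu_y) / sd_y
    params["__response__"] = (mu_y, sd_y)
    out = PredictorSet(
        dict(predictors.matrices), standardized=True, scale_params=params,
        vif_removed=dict(predictors.vif_removed),
    )
    return vectors, y, out


def vif_screen(
    vectors: dict[str, np.ndarray], threshold: float = 5.0
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Iteratively remove the predictor with the largest VIF above threshold.

    VIF_j = 1/(1 - R^2_j), with R^2_j from the OLS regression of predictor
    j's unfolded vector on all other retained predictors (plus intercept).
    Ties on the maximal VIF drop the later predictor in declared order.
    Returns the retained vectors and a log of removals {name: VIF}.
    """
    retained = dict(vectors)
    removed: dict[str, float] = {}
    while len(retained) > 1:
        vifs = {}
        names = list(retained)
        for name in names:
            others = np.column_stack(
                [retained[o] for o in names if o != name]
            )
            X = np.column_stack([np.ones(len(others)), others])
            y = retained[name]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # on ties, drop the later predictor in declared order
        victim = [n for n in names if vifs[n] == worst][-1]
        removed[victim] = vifs[victim]
        del retained[victim]
    if not retained:
        raise ValidationError("VIF screen removed every predictor")
    return retained, removed
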