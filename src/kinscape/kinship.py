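"""Pairwise kinship from dominant binary markers.

Dominant markers (band presence/absence) hide the distinction between
heterozygotes and dominant homozygotes. Assuming Hardy-Weinberg
equilibrium, the band frequency f at a locus satisfies f = 1 - (1-p)^2,
so the presence-allele frequency is recovered as p = 1 - sqrt(1 - f),
and each phenotype maps to an expected allele dosage (on the per-gene-copy
scale): band absent -> 0 (genotype must be aa), band present ->
1/(2 - p), the HWE-conditional expectation of half the diploid dosage.

Kinship is then a Loiselle-type moment estimator on these dosage
expectations, referenced to the sample allele frequencies and with a
small-sample correction equal to the empirical dosage variance divided
by (n - 1). The correction makes the estimator exactly centred: the
off-diagonal mean is 0 for complete data by construction. For codominant
per-copy indicators the dosage variance is p(1-p), so the term reduces
to the classical Loiselle correction; the binomial form p(1-p)/(n-1) is
retained as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, KinscapeError, ValidationError

__all__ = [
    "PairwiseMatrix",
    "LocusFrequencies",
    "estimate_frequencies",
    "kinship_matrix",
    "write_pairwise",
    "read_pairwise",
]


@dataclass
class PairwiseMatrix:
    """Symmetric n x n matrix over individuals (kinship or dissimilarity).

    ``kind`` is one of ``kinship``, ``distance``, ``dissimilarity``.
    Kinship matrices carry NaN on the diagonal (self-kinship is unused
    downstream); distance/dissimilarity matrices have a zero diagonal and
    non-negative entries, with Jaccard dissimilarities additionally <= 1.
    """

    individual_ids: list[str]
    values: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate ids in pairwise matrix")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"pairwise matrix shape {self.values.shape} != ({n}, {n})"
            )
        if self.kind not in ("kinship", "distance", "dissimilarity"):
            raise ValidationError(f"unknown pairwise matrix kind {self.kind!r}")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(
            self.values[off], self.values.T[off], atol=1e-12, rtol=0, equal_nan=True
        ):
            raise ValidationError("pairwise matrix is not symmetric")
        if self.kind in ("distance", "dissimilarity"):
            if not np.allclose(np.diag(self.values), 0, atol=1e-12):
                raise ValidationError(f"{self.kind} matrix diagonal must be 0")
            if (self.values[off] < -1e-12).any():
                raise ValidationError(f"{self.kind} entries must be >= 0")

    @property
    def n(self) -> int:
        return len(self.individual_ids)


@dataclass
class LocusFrequencies:
    """Per-locus band frequency, allele frequency and dosage expectations."""

    locus_ids: list[str]
    f_band: np.ndarray        #: observed band (phenotype 1) frequency
    p: np.ndarray             #: presence-allele frequency, 1 - sqrt(1 - f_band)
    dosage_present: np.ndarray  #: E[per-copy dosage | band present] = 1/(2 - p)
    n_obs: np.ndarray         #: non-missing sample size per locus


def estimate_frequencies(genotypes: GenotypeMatrix) -> LocusFrequencies:
    """HWE-based allele frequencies and conditional dosage expectations.

    Loci must be polymorphic (f_band strictly inside (0, 1)); fixed loci
    should have been removed by :func:`kinscape.io_formats.drop_monomorphic`.
    """
    vals = genotypes.values
    n_obs = (~np.isnan(vals)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f_band = np.nanmean(vals, axis=0)
    fixed = (f_band <= 0) | (f_band >= 1) | (n_obs == 0)
    if fixed.any():
        bad = [genotypes.locus_ids[j] for j in np.flatnonzero(fixed)]
        raise ValidationError(
            f"monomorphic or empty loci present (drop them first): {bad[:5]}"
        )
    p = 1.0 - np.sqrt(1.0 - f_band)
    return LocusFrequencies(
        locus_ids=list(genotypes.locus_ids),
        f_band=f_band,
        p=p,
        dosage_present=1.0 / (2.0 - p),
        n_obs=n_obs,
    )


def kinship_matrix(
    genotypes: GenotypeMatrix,
    freqs: LocusFrequencies | None = None,
    correction: str = "dosage_variance",
) -> PairwiseMatrix:
    """Loiselle-type kinship coefficients between all individual pairs.

    F_ij = sum_l [ (x_il - p_l)(x_jl - p_l) + c_l/(n_l - 1) ]
           / sum_l p_l (1 - p_l)

    where x is the HWE dosage expectation, sums run over loci non-missing
    in both individuals, n_l is the non-missing sample size at locus l and
    c_l is the small-sample correction: the empirical variance of x at
    locus l (``correction="dosage_variance"``, exactly centred) or the
    binomial variance p_l(1 - p_l) (``correction="binomial"``).

    The diagonal is NaN; pairs sharing no locus raise an error.
    """
    if freqs is None:
        freqs = estimate_frequencies(genotypes)
    if correction not in ("dosage_variance", "binomial"):
        raise ValidationError(f"unknown correction {correction!r}")
    vals = genotypes.values
    n, L = vals.shape
    if n < 2:
        raise ValidationError("kinship needs at least 2 individuals")

    # dosage expectations: 0 stays 0, 1 -> 1/(2 - p); NaN propagates
    x = vals * freqs.dosage_present[None, :]
    obs = ~np.isnan(vals)
    dev = np.where(obs, x - freqs.p[None, :], 0.0)

    pq = freqs.p * (1.0 - freqs.p)
    if correction == "dosage_variance":
        # ML variance of the dosage expectations about p (not about mean(x);
        # the two coincide because mean(x) = p exactly under the HWE mapping)
        var = (dev**2).sum(axis=0) / freqs.n_obs
    else:
        var = pq
    corr = var / (freqs.n_obs - 1.0)

    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T                      # loci observed in both
    if (shared[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))[0]
        raise KinscapeError(
            f"individuals {genotypes.individual_ids[i]!r} and "
            f"{genotypes.individual_ids[j]!r} share no non-missing locus"
        )
    numer = dev @ dev.T + obs_f @ (corr[:, None] * obs_f.T)
    denom = obs_f @ (pq[:, None] * obs_f.T)
    F = numer / denom
    F = (F + F.T) / 2.0                           # kill floating asymmetry
    np.fill_diagonal(F, np.nan)
    return PairwiseMatrix(list(genotypes.individual_ids), F, kind="kinship")


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_pairwise(matrix: PairwiseMatrix, path, long_format: bool = False) -> None:
    """Write a pairwise matrix as square delimited text (or long format)."""
    import pandas as pd

    if long_format:
        rows = []
        ids = matrix.individual_ids
        for i in range(matrix.n):
            for j in range(i):
                rows.append({"id_i": ids[i], "id_j": ids[j],
                             "value": matrix.values[i, j]})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        df = pd.DataFrame(
            matrix.values, index=matrix.individual_ids, columns=matrix.individual_ids
        )
        df.index.name = f"kind={matrix.kind}"
        df.to_csv(path)


def read_pairwise(path, kind: str = "kinship") -> PairwiseMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if df.index.name and df.index.name.startswith("kind="):
        kind = df.index.name.split("=", 1)[1]
    return PairwiseMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), kind)
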