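"""End-to-end isolation-by-distance / environment / community analysis.

Orchestrates the full procedure for one species' dataset: genotype QC,
kinship estimation, predictor construction, standardization, collinearity
screening, all-subsets AICc model averaging, Mantel-style permutation
inference and FDR control, ending in an effects table that classifies
every predictor as "isolation", "counter-gradient" or "none".

Two designs are supported, mirroring the coarse and fine views of the
environment:

* ``mode="three"`` — geography + one PCA-combined environmental distance
  + community dissimilarity (3 predictors, 8 submodels);
* ``mode="twelve"`` — geography + community + one distance matrix per
  environmental variable (12 predictors before VIF screening).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, predictors as pred_mod
from .inference import attach_inference, permutation_test
from .io_formats import (
    AssociationLookup,
    GenotypeMatrix,
    SampleTable,
    ValidationError,
    read_association_lookup,
    read_genotypes,
    read_samples,
)
from .kinship import PairwiseMatrix, estimate_frequencies, kinship_matrix
from .model_averaging import SubsetEngine, average_effects
from .predictors import (
    PredictorSet,
    combined_environment_distance,
    community_distance,
    geographic_distances,
    per_variable_distances,
    standardize_predictors,
    vif_screen,
)

logger = logging.getLogger("kinscape")

__all__ = ["RunConfig", "RunResult", "run_analysis", "compare_modes",
           "EFFECT_COLUMNS"]

EFFECT_COLUMNS = [
    "run_id", "predictor", "estimate", "se", "ci_lo", "ci_hi",
    "significant_ci", "z", "p", "q", "significant_final", "direction",
]


@dataclass
class RunConfig:
    """Everything one reproducible analysis run depends on."""

    mode: str = "three"               #: "three" or "twelve"
    run_id: str = "run"
    genotypes_path: str | None = None
    samples_path: str | None = None
    associations_path: str | None = None
    variables: list[str] | None = None  #: env variables (default: all in table)
    permutations: int = 1000
    vif_threshold: float = 5.0
    fdr_level: float = 0.05
    kinship_correction: str = "dosage_variance"
    averaging: str = "conditional"
    p_source: str = "empirical"
    distance_method: str = "haversine"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("three", "twelve"):
            raise ValidationError(f"mode must be 'three' or 'twelve', got {self.mode!r}")


@dataclass
class RunResult:
    effects: pd.DataFrame
    report: dict
    kinship: PairwiseMatrix


def _align(genotypes: GenotypeMatrix, samples: SampleTable) -> SampleTable:
    g_ids, s_ids = set(genotypes.individual_ids), set(samples.ids)
    if g_ids != s_ids:
        only_g = sorted(g_ids - s_ids)
        only_s = sorted(s_ids - g_ids)
        raise ValidationError(
            "genotype/sample id mismatch: "
            f"only in genotypes {only_g[:10]}, only in samples {only_s[:10]}"
        )
    order = pd.Categorical(
        samples.data["id"], categories=genotypes.individual_ids, ordered=True
    )
    df = samples.data.iloc[np.argsort(order.codes)].reset_index(drop=True)
    return SampleTable(df)


def _build_predictors(
    samples: SampleTable,
    lookup: AssociationLookup,
    config: RunConfig,
) -> PredictorSet:
    variables = config.variables or samples.env_names
    matrices: dict[str, PairwiseMatrix] = {
        "geography": geographic_distances(samples, method=config.distance_method)
    }
    if config.mode == "three":
        matrices["environment_combined"] = combined_environment_distance(
            samples, variables
        )
    else:
        for name, m in per_variable_distances(samples, variables).matrices.items():
            matrices[name] = m
    matrices["community"] = community_distance(samples, lookup)
    return PredictorSet(matrices)


def run_analysis(
    config: RunConfig,
    genotypes: GenotypeMatrix | None = None,
    samples: SampleTable | None = None,
    lookup: AssociationLookup | None = None,
) -> RunResult:
    """Run one complete analysis; inputs in memory or from config paths.

    Returns the effects table (one row per predictor, column contract in
    ``EFFECT_COLUMNS``) and a report recording every QC and screening
    decision. When ``config.output_dir`` is set, ``effects.csv`` and
    ``run_report.json`` are written there deterministically.
    """
    if genotypes is None:
        if config.genotypes_path is None:
            raise ValidationError("no genotypes given (in memory or by path)")
        genotypes = read_genotypes(config.genotypes_path)
    if samples is None:
        if config.samples_path is None:
            raise ValidationError("no sample table given")
        samples = read_samples(config.samples_path)
    if lookup is None:
        if config.associations_path is None:
            raise ValidationError("no association lookup given")
        lookup = read_association_lookup(config.associations_path)

    n_loci_in = genotypes.n_loci
    genotypes, mono_report = io_formats.drop_monomorphic(genotypes)
    samples = _align(genotypes, samples)
    lookup.validate_covers(samples)

    freqs = estimate_frequencies(genotypes)
    K = kinship_matrix(genotypes, freqs, correction=config.kinship_correction)

    pset = _build_predictors(samples, lookup, config)
    vectors, y, pset = standardize_predictors(pset, K)

    vif_removed: dict[str, float] = {}
    if config.mode == "twelve":
        vectors, vif_removed = vif_screen(vectors, threshold=config.vif_threshold)
        for name, v in vif_removed.items():
            logger.info("VIF screen removed %r (VIF = %.2f)", name, v)

    engine = SubsetEngine(vectors)
    fits = engine.fit(y)
    effects = average_effects(fits, method=config.averaging)
    perm = permutation_test(
        K_standardized(y, K), vectors, B=config.permutations, seed=config.seed,
    )
    attach_inference(
        effects, perm, level=config.fdr_level, p_source=config.p_source
    )

    rows = []
    for e in effects:
        rows.append(
            {
                "run_id": config.run_id,
                "predictor": e.term,
                "estimate": e.estimate,
                "se": e.se,
                "ci_lo": e.ci_lo,
                "ci_hi": e.ci_hi,
                "significant_ci": e.significant_ci,
                "z": e.z,
                "p": e.p_empirical if config.p_source == "empirical" else e.p_normal,
                "q": e.q,
                "significant_final": e.significant_final,
                "direction": e.direction,
            }
        )
    table = pd.DataFrame(rows, columns=EFFECT_COLUMNS)

    from . import __version__

    report = {
        "run_id": config.run_id,
        "package_version": __version__,
        "config": asdict(config),
        "n_individuals": genotypes.n_individuals,
        "n_loci_input": n_loci_in,
        "n_loci_retained": genotypes.n_loci,
        "monomorphic_dropped": sorted(mono_report.dropped),
        "n_pairs": len(y),
        "predictors": list(vectors),
        "vif_removed": {k: float(v) for k, v in vif_removed.items()},
        "n_submodels": len(fits),
        "permutations": config.permutations,
        "seed": config.seed,
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "effects.csv", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return RunResult(effects=table, report=report, kinship=K)


def K_standardized(y: np.ndarray, K: PairwiseMatrix) -> PairwiseMatrix:
    """Refold the standardized kinship vector so permutations relabel it."""
    from .model_averaging import refold

    return refold(y, list(K.individual_ids), kind="kinship")


# ---------------------------------------------------------------------------
# three-vs-twelve concordance
# ---------------------------------------------------------------------------

_ISOLATION_CLASSES = ("D", "E", "C")


def _classify(effects: pd.DataFrame, mode: str) -> dict[str, str]:
    """Collapse an effects table to the D/E/C isolation classes.

    E in twelve mode means *any* environmental variable; a class is
    "isolation" if any member predictor is, else "counter-gradient" if
    any is, else "none".
    """
    def best(directions: list[str]) -> str:
        if "isolation" in directions:
            return "isolation"
        if "counter-gradient" in directions:
            return "counter-gradient"
        return "none"

    env_preds = [
        p for p in effects["predictor"]
        if p not in ("geography", "community")
    ]
    groups = {
        "D": ["geography"],
        "E": env_preds,
        "C": ["community"],
    }
    out = {}
    for cls, names in groups.items():
        sub = effects[effects["predictor"].isin(names)]
        out[cls] = best(list(sub["direction"]))
    return out


def compare_modes(
    effects_three: pd.DataFrame, effects_twelve: pd.DataFrame
) -> pd.DataFrame:
    """Concordance of the D/E/C isolation classes between the two designs.

    Both tables must come from the same dataset (matching run ids after
    stripping a trailing mode suffix is not required — ids must intersect).
    """
    ids3 = set(effects_three["run_id"].str.replace(r"[-_](three|twelve)$", "", regex=True))
    ids12 = set(effects_twelve["run_id"].str.replace(r"[-_](three|twelve)$", "", regex=True))
    if not ids3 & ids12:
        raise ValidationError(
            f"run ids do not overlap: {sorted(ids3)} vs {sorted(ids12)}"
        )
    c3 = _classify(effects_three, "three")
    c12 = _classify(effects_twelve, "twelve")
    rows = [
        {
            "class": cls,
            "three": c3[cls],
            "twelve": c12[cls],
            "concordant": c3[cls] == c12[cls],
        }
        for cls in _ISOLATION_CLASSES
    ]
    return pd.DataFrame(rows)
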