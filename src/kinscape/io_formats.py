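"""Input/output formats and genotype quality control.

Handles every external representation the pipeline touches:

* genotype tables — individuals x loci binary dominant phenotypes
  (band presence/absence, e.g. AFLP scores), missing values allowed;
* sample tables — per-individual coordinates, environmental variables
  and a vegetation-association label;
* ESRI ASCII rasters, for extracting environment or association class
  at sampled GPS positions;
* association -> species lookup tables (long format).

QC filters implemented here: removal of loci with excess mismatches
between replicate genotyping runs, and removal of monomorphic loci
(pairwise kinship is undefined at fixed loci).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kinscape")

#: token written for missing genotypes / NODATA extractions
DEFAULT_MISSING_TOKEN = ""


class KinscapeError(Exception):
    """Base class for validation and numerical errors raised by this package."""


class ValidationError(KinscapeError):
    """Input data violates a documented invariant."""


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Binary dominant phenotypes for n individuals at L loci.

    ``values`` is a float array with entries 0.0, 1.0 or NaN (missing).
    A 1 means the marker band was observed; under dominance this is the
    union of heterozygote and dominant-homozygote genotypes.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = _duplicates(self.individual_ids)
            raise ValidationError(f"duplicate individual id(s): {sorted(dupes)}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            dupes = _duplicates(self.locus_ids)
            raise ValidationError(f"duplicate locus id(s): {sorted(dupes)}")
        if len(self.individual_ids) < 2:
            raise ValidationError("need at least 2 individuals")
        if self.values.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValidationError(
                f"genotype array shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"non-binary genotype value {self.values[i, j]!r} for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def row(self, individual_id: str) -> np.ndarray:
        return self.values[self.individual_ids.index(individual_id)]

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.locus_ids[j] for j in keep],
            self.values[:, keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.locus_ids
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    return {x for x in items if x in seen or seen.add(x)}


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_genotypes(
    path: str | Path,
    delimiter: str | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> GenotypeMatrix:
    """Read a delimited genotype table (first column id, header of locus ids).

    Delimiter is auto-detected between comma and tab unless given. Entries
    must be 0, 1 or the missing token (empty string by default).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    ids = [str(i) for i in df.index]
    loci = [str(c) for c in df.columns]
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok == missing_token or tok == "":
                continue
            if tok == "0":
                values[i, j] = 0.0
            elif tok == "1":
                values[i, j] = 1.0
            else:
                raise ValidationError(
                    f"non-binary genotype token {tok!r} at row {ids[i]!r}, "
                    f"column {loci[j]!r} in {path}"
                )
    gm = GenotypeMatrix(ids, loci, values)
    logger.info(
        "read %d individuals x %d loci from %s (%d missing entries)",
        gm.n_individuals, gm.n_loci, path, gm.n_missing,
    )
    return gm


def write_genotypes(
    genotypes: GenotypeMatrix,
    path: str | Path,
    delimiter: str = ",",
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write a genotype table in the format :func:`read_genotypes` reads."""
    df = genotypes.to_frame()
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.index.name = "id"
    out.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# Replicate-based locus filter
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    """Re-extracted, re-genotyped copies of a subset of individuals.

    ``replicates`` maps individual id -> replicate genotype row over the
    same locus set (and order) as the main matrix it will be compared to.
    """

    locus_ids: list[str]
    replicates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.locus_ids = [str(l) for l in self.locus_ids]
        L = len(self.locus_ids)
        for ind, row in self.replicates.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (L,):
                raise ValidationError(
                    f"replicate row for {ind!r} has length {row.shape}, expected {L}"
                )
            self.replicates[ind] = row


@dataclass
class LocusFilterReport:
    """Which loci a QC step dropped, and why."""

    dropped: list[str] = field(default_factory=list)
    reason: dict[str, str] = field(default_factory=dict)


def filter_loci_by_replicates(
    genotypes: GenotypeMatrix,
    reps: ReplicateSet,
    max_mismatches: int = 1,
) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Drop loci whose replicate mismatch count exceeds ``max_mismatches``.

    For each replicated individual, a locus mismatches when the original
    and replicate scores are both non-missing and differ. By default the
    counts are summed over all replicate pairs and loci with more than one
    mismatch are removed; set ``per_pair`` semantics by lowering
    ``max_mismatches`` to 0 if a single mismatch anywhere should disqualify.
    """
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    if reps.locus_ids != genotypes.locus_ids:
        raise ValidationError("replicate locus set does not match genotype loci")
    mismatches = np.zeros(genotypes.n_loci)
    for ind, rep_row in reps.replicates.items():
        if ind not in genotypes.individual_ids:
            raise ValidationError(f"replicate individual {ind!r} absent from genotypes")
        orig = genotypes.row(ind)
        both = ~np.isnan(orig) & ~np.isnan(rep_row)
        mismatches += both & (orig != rep_row)
    keep = [j for j in range(genotypes.n_loci) if mismatches[j] <= max_mismatches]
    report = LocusFilterReport()
    for j in range(genotypes.n_loci):
        if mismatches[j] > max_mismatches:
            name = genotypes.locus_ids[j]
            report.dropped.append(name)
            report.reason[name] = f"{int(mismatches[j])} replicate mismatches"
    logger.info(
        "replicate filter: dropped %d/%d loci", len(report.dropped), genotypes.n_loci
    )
    return genotypes.subset_loci(keep), report


def drop_monomorphic(
    genotypes: GenotypeMatrix,
) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Remove loci fixed for 0 or 1 among non-missing scores."""
    keep: list[int] = []
    report = LocusFilterReport()
    for j in range(genotypes.n_loci):
        col = genotypes.values[:, j]
        col = col[~np.isnan(col)]
        if col.size > 0 and col.min() != col.max():
            keep.append(j)
        else:
            name = genotypes.locus_ids[j]
            report.dropped.append(name)
            report.reason[name] = "monomorphic"
    if not keep:
        raise ValidationError("no polymorphic loci")
    logger.info(
        "monomorphic filter: dropped %d/%d loci", len(report.dropped), genotypes.n_loci
    )
    return genotypes.subset_loci(keep), report


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-individual position, environment and vegetation association.

    Backed by a DataFrame with columns ``id``, ``lon``, ``lat``,
    ``association`` and one numeric column per environmental variable.
    """

    data: pd.DataFrame

    MANDATORY = ("id", "lon", "lat", "association")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.MANDATORY if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing column(s): {missing}")
        df = df.copy()
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = sorted(df.loc[df["id"].duplicated(), "id"])
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        for c in ("lon", "lat"):
            df[c] = pd.to_numeric(df[c])
            if not np.isfinite(df[c]).all():
                raise ValidationError(f"non-finite {c} coordinate")
        if (df["lat"].abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (df["lon"].abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        for c in self.env_names_of(df):
            df[c] = pd.to_numeric(df[c])
        self.data = df.reset_index(drop=True)

    @staticmethod
    def env_names_of(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in SampleTable.MANDATORY]

    @property
    def ids(self) -> list[str]:
        return list(self.data["id"])

    @property
    def env_names(self) -> list[str]:
        return self.env_names_of(self.data)

    @property
    def env(self) -> pd.DataFrame:
        return self.data.set_index("id")[self.env_names]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat) in decimal degrees."""
        return self.data[["lon", "lat"]].to_numpy(dtype=float)

    @property
    def association(self) -> pd.Series:
        return self.data.set_index("id")["association"].astype(str)


def read_samples(path: str | Path, delimiter: str | None = None) -> SampleTable:
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    return SampleTable(pd.read_csv(path, sep=delimiter))


def write_samples(samples: SampleTable, path: str | Path, delimiter: str = ",") -> None:
    samples.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Association -> species lookup
# ---------------------------------------------------------------------------

@dataclass
class AssociationLookup:
    """Maps each vegetation-association label to its set of co-occurring species."""

    species: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for assoc, spp in self.species.items():
            spp = frozenset(str(s) for s in spp)
            if not spp:
                raise ValidationError(f"association {assoc!r} has an empty species set")
            clean[str(assoc)] = spp
        self.species = clean

    def __getitem__(self, assoc: str) -> frozenset[str]:
        try:
            return self.species[assoc]
        except KeyError:
            raise ValidationError(f"association {assoc!r} has no lookup entry") from None

    def validate_covers(self, samples: SampleTable) -> None:
        missing = sorted(set(samples.association) - set(self.species))
        if missing:
            raise ValidationError(f"associations without lookup entry: {missing}")


def read_association_lookup(path: str | Path, delimiter: str | None = None) -> AssociationLookup:
    """Read a long-format table with columns ``association`` and ``species``."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for c in ("association", "species"):
        if c not in df.columns:
            raise ValidationError(f"association lookup missing column {c!r}")
    grouped = df.groupby("association")["species"].apply(frozenset).to_dict()
    return AssociationLookup(grouped)


def write_association_lookup(
    lookup: AssociationLookup, path: str | Path, delimiter: str = ","
) -> None:
    rows = [
        {"association": a, "species": s}
        for a in sorted(lookup.species)
        for s in sorted(lookup.species[a])
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """ESRI ASCII grid: row-major cell values, first data row northernmost."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray  # (nrows, ncols), row 0 = north

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValidationError(
                f"raster shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be > 0")


def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
        else:
            rows.append([float(x) for x in parts])
    nodata = header.get("nodata_value", -9999.0)
    return RasterGrid(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=nodata,
        values=np.array(rows, dtype=float),
    )


def write_raster(raster: RasterGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {float(raster.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(raster.yllcorner)!r}\n")
        fh.write(f"cellsize {float(raster.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata_value)!r}\n")
        for r in range(raster.nrows):
            fh.write(" ".join(repr(float(v)) for v in raster.values[r]) + "\n")


def extract_at_points(
    raster: RasterGrid, points: Sequence[tuple[float, float]]
) -> list[float]:
    """Value of the raster cell containing each (x, y) point.

    Cell membership uses half-open intervals
    ``[xll + j*cellsize, xll + (j+1)*cellsize)`` in both axes, so a point on
    a shared edge belongs to the higher-index cell. NODATA cells yield NaN.
    """
    out: list[float] = []
    for x, y in points:
        j = math.floor((x - raster.xllcorner) / raster.cellsize)
        i_from_south = math.floor((y - raster.yllcorner) / raster.cellsize)
        if not (0 <= j < raster.ncols) or not (0 <= i_from_south < raster.nrows):
            raise ValidationError(f"point ({x}, {y}) outside raster bounds")
        i = raster.nrows - 1 - i_from_south  # row 0 is the northernmost
        v = raster.values[i, j]
        if v == raster.nodata_value:
            logger.warning("point (%s, %s) falls in a NODATA cell", x, y)
            out.append(float("nan"))
        else:
            out.append(float(v))
    return out
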