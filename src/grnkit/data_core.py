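"""Data model, I/O and summary statistics for single-cell transcript counts.

The central object is :class:`ExpressionDataset`, a validated long-format
table of per-cell mRNA spot counts annotated with gene, genotype, timepoint,
animal and cell-lineage labels.  Summary statistics (bootstrap means/SDs,
Fano factor, coefficient of variation, paired-cell correlation) feed the
downstream network-inference stages.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENES",
    "TIMEPOINTS",
    "REQUIRED_COLUMNS",
    "ExpressionRecord",
    "ExpressionDataset",
    "GenotypeSpec",
    "SummaryStats",
    "DataFormatError",
    "DataValidationError",
    "InsufficientDataError",
    "read_dataset",
    "write_dataset",
    "summarize_expression",
    "summary_frame",
    "fano_factor",
    "coefficient_of_variation",
    "paired_cell_correlation",
    "genotype_activities",
]

#: canonical gene order (gene 1, gene 2, gene 3)
GENES: tuple[str, ...] = ("elt-1", "egl-18", "ceh-16")

TIMEPOINTS: tuple[str, ...] = ("early-L1", "late-L1", "early-L2", "late-L2")

REQUIRED_COLUMNS = ("gene", "genotype", "timepoint", "animal_id", "cell_id", "count")

#: canonical seam-cell lineage labels used by the default filter
V_LINEAGES = frozenset({"V1", "V2", "V3", "V4"})

WILD_TYPE = "wild type"

#: single-mutant genotype label per gene
MUTANT_OF = {
    "elt-1": "elt-1(ku491)",
    "egl-18": "egl-18(ga97)",
    "ceh-16": "ceh-16(bp323)",
}

DOUBLE_MUTANT = "egl-18(ga97);ceh-16(bp323)"

#: default activity fractions of the mutated protein, by inference stage.
#: "partial" covers the hypomorphic alleles, "null" the complete
#: loss-of-function allele.  The two stages use different null defaults.
STAGE_ACTIVITY_DEFAULTS = {
    "mra": {"partial": 0.25, "null": 1e-4},
    "ode": {"partial": 0.25, "null": 0.01},
}

#: allele class per gene
ALLELE_CLASS = {"elt-1": "partial", "egl-18": "null", "ceh-16": "partial"}


class DataFormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class DataValidationError(ValueError):
    """Raised when record contents violate the data contract."""


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested on too little data."""


@dataclasses.dataclass(frozen=True)
class ExpressionRecord:
    """A single per-cell mRNA count."""

    gene: str
    genotype: str
    timepoint: str
    animal_id: str
    cell_id: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise DataValidationError(
                f"count must be a non-negative integer, got {self.count!r}"
            )


@dataclasses.dataclass(frozen=True)
class GenotypeSpec:
    """Genotype with per-gene protein-activity fractions (wild type = 1)."""

    name: str
    activities: tuple[float, ...]

    def __post_init__(self) -> None:
        for a in self.activities:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"activity {a} outside [0, 1] in {self.name!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.activities, dtype=float)


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    """Per gene x genotype (x timepoint) expression summary."""

    gene: str
    genotype: str
    timepoint: str
    mean: float            # bootstrap mean of per-resample means
    sd: float              # bootstrap SD of the mean
    fano: float
    cv: float
    paired_correlation: float  # NaN when not computable
    n_cells: int


class ExpressionDataset:
    """Long-format single-cell count data with declared gene/genotype order.

    Thin wrapper around a validated :class:`pandas.DataFrame` with the
    columns of :data:`REQUIRED_COLUMNS`.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        genes: Sequence[str] | None = None,
        genotypes: Sequence[str] | None = None,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {missing}")
        frame = frame.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        counts = frame["count"]
        numeric = pd.to_numeric(counts, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"row {row}: count {counts.iloc[row]!r} is not a non-negative integer"
            )
        frame["count"] = numeric.astype(int)
        for col in REQUIRED_COLUMNS[:-1]:
            frame[col] = frame[col].astype(str)

        self._frame = frame
        self.genes = tuple(genes) if genes is not None else tuple(
            dict.fromkeys(frame["gene"])
        )
        self.genotypes = tuple(genotypes) if genotypes is not None else tuple(
            dict.fromkeys(frame["genotype"])
        )
        unknown_genes = set(frame["gene"]) - set(self.genes)
        if unknown_genes:
            raise DataValidationError(f"genes not in declared list: {unknown_genes}")
        unknown_gt = set(frame["genotype"]) - set(self.genotypes)
        if unknown_gt:
            raise DataValidationError(f"genotypes not in declared list: {unknown_gt}")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.genotypes == other.genotypes
            and self._frame.equals(other._frame)
        )

    def records(self) -> list[ExpressionRecord]:
        return [
            ExpressionRecord(**row)  # type: ignore[arg-type]
            for row in self._frame.to_dict("records")
        ]

    def filter_lineage(self, lineages: Iterable[str]) -> "ExpressionDataset":
        keep = self._frame["cell_id"].isin(set(lineages))
        return ExpressionDataset(self._frame[keep], self.genes, self.genotypes)

    def group_counts(self, gene: str, genotype: str, timepoint: str) -> np.ndarray:
        f = self._frame
        sel = (
            (f["gene"] == gene)
            & (f["genotype"] == genotype)
            & (f["timepoint"] == timepoint)
        )
        return f.loc[sel, "count"].to_numpy()


def read_dataset(
    path: str | Path,
    lineage_filter: Iterable[str] | None = None,
    genes: Sequence[str] | None = None,
    genotypes: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Read a count table from CSV, optionally keeping only some lineages.

    The header must declare ``gene,genotype,timepoint,animal_id,cell_id,count``.
    Rows whose ``cell_id`` is not in ``lineage_filter`` are dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s): {missing}")
    ds = ExpressionDataset(frame, genes=genes, genotypes=genotypes)
    if lineage_filter is not None:
        ds = ds.filter_lineage(lineage_filter)
    return ds


def write_dataset(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to CSV (round-trips exactly)."""
    dataset.frame.to_csv(path, index=False)


def fano_factor(values: Sequence[float] | np.ndarray) -> float:
    """Sample variance (ddof=1) divided by the mean; 1 for a Poisson process."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("fano_factor needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("fano_factor undefined for zero-mean data")
    return float(values.var(ddof=1) / mean)


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """Sample SD (ddof=1) divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("coefficient_of_variation needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("coefficient_of_variation undefined for zero-mean data")
    return float(values.std(ddof=1) / mean)


def bootstrap_mean_sd(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and SD of per-resample means under cell-level resampling."""
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1)) if n_boot > 1 else 0.0


def bootstrap_mean_sd_by_animal(
    values: np.ndarray, animals: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and SD of per-resample means, resampling whole animals.

    Respects the within-animal correlation induced by extrinsic noise, so
    the SD is a less optimistic standard error than cell-level resampling.
    """
    values = np.asarray(values, dtype=float)
    uniq, inverse = np.unique(np.asarray(animals), return_inverse=True)
    per_animal_sum = np.bincount(inverse, weights=values, minlength=len(uniq))
    per_animal_n = np.bincount(inverse, minlength=len(uniq)).astype(float)
    A = len(uniq)
    idx = rng.integers(0, A, size=(n_boot, A))
    means = per_animal_sum[idx].sum(axis=1) / per_animal_n[idx].sum(axis=1)
    return float(means.mean()), float(means.std(ddof=1)) if n_boot > 1 else 0.0


def summarize_expression(
    dataset: ExpressionDataset,
    timepoint: str,
    n_boot: int = 1000,
    seed: int = 0,
    boot_unit: str = "cell",
) -> dict[tuple[str, str], SummaryStats]:
    """Bootstrap summary statistics per gene x genotype at one timepoint.

    With ``boot_unit='cell'`` (default) cells are resampled with replacement
    within each gene x genotype group; ``'animal'`` resamples whole animals,
    acknowledging the within-animal correlation of counts.  The reported
    mean is the average of per-resample means and the SD is the standard
    deviation of those means (the bootstrap SE of the mean).
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if boot_unit not in ("cell", "animal"):
        raise ValueError(f"boot_unit must be 'cell' or 'animal', got {boot_unit!r}")
    rng = np.random.default_rng(seed)
    f = dataset.frame
    out: dict[tuple[str, str], SummaryStats] = {}
    for gene in dataset.genes:
        for genotype in dataset.genotypes:
            sel = (
                (f["gene"] == gene)
                & (f["genotype"] == genotype)
                & (f["timepoint"] == timepoint)
            )
            counts = f.loc[sel, "count"].to_numpy()
            if counts.size == 0:
                raise InsufficientDataError(
                    f"no cells for gene={gene!r} genotype={genotype!r} "
                    f"at timepoint={timepoint!r}"
                )
            if boot_unit == "animal":
                animals = f.loc[sel, "animal_id"].to_numpy()
                mu, sd = bootstrap_mean_sd_by_animal(counts, animals, n_boot, rng)
            else:
                mu, sd = bootstrap_mean_sd(counts, n_boot, rng)
            mean = counts.mean()
            fano = counts.var(ddof=1) / mean if counts.size > 1 and mean > 0 else 0.0
            cv = counts.std(ddof=1) / mean if counts.size > 1 and mean > 0 else 0.0
            try:
                rho = paired_cell_correlation(dataset, gene, genotype, timepoint)
            except InsufficientDataError:
                rho = float("nan")
            out[(gene, genotype)] = SummaryStats(
                gene=gene,
                genotype=genotype,
                timepoint=timepoint,
                mean=mu,
                sd=sd,
                fano=float(fano),
                cv=float(cv),
                paired_correlation=rho,
                n_cells=int(counts.size),
            )
    return out


def summary_frame(stats: Mapping[tuple[str, str], SummaryStats]) -> pd.DataFrame:
    """Summary statistics as a tidy one-row-per-group DataFrame."""
    return pd.DataFrame([dataclasses.asdict(s) for s in stats.values()])


def paired_cell_correlation(
    dataset: ExpressionDataset,
    gene: str,
    genotype: str,
    timepoint: str,
    rng: np.random.Generator | None = None,
) -> float:
    """Pearson correlation of same-gene counts between two cells per animal.

    By default the two cells with the lexicographically lowest lineage labels
    are paired (deterministic); pass ``rng`` to pick two cells at random when
    an animal contributes more than two.
    """
    f = dataset.frame
    sel = (
        (f["gene"] == gene)
        & (f["genotype"] == genotype)
        & (f["timepoint"] == timepoint)
    )
    sub = f.loc[sel]
    first, second = [], []
    for _, grp in sub.groupby("animal_id", sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("cell_id", kind="stable")
        if rng is not None and len(grp) > 2:
            pick = rng.choice(len(grp), size=2, replace=False)
            pick.sort()
            pair = grp.iloc[pick]
        else:
            pair = grp.iloc[:2]
        first.append(pair["count"].iloc[0])
        second.append(pair["count"].iloc[1])
    if len(first) < 3:
        raise InsufficientDataError(
            f"paired correlation needs >=3 animals with >=2 cells for "
            f"gene={gene!r} genotype={genotype!r} timepoint={timepoint!r}"
        )
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise InsufficientDataError("paired correlation undefined for constant pairs")
    return float(np.corrcoef(a, b)[0, 1])


def genotype_activities(
    genotype: str,
    stage: str = "ode",
    overrides: Mapping[str, Mapping[str, float]] | None = None,
    genes: Sequence[str] = GENES,
) -> GenotypeSpec:
    """Resolve a genotype name to per-gene activity fractions.

    ``stage`` selects the null/partial defaults ('mra': 0.25 / 1e-4,
    'ode': 0.25 / 0.01).  ``overrides`` maps genotype name to an explicit
    ``{gene: activity}`` mapping and takes precedence; it is also the only
    way to introduce genotypes whose names do not embed known gene names.
    """
    if overrides and genotype in overrides:
        table = overrides[genotype]
        acts = tuple(float(table.get(g, 1.0)) for g in genes)
        return GenotypeSpec(genotype, acts)
    if stage not in STAGE_ACTIVITY_DEFAULTS:
        raise ValueError(f"unknown stage {stage!r}; expected 'mra' or 'ode'")
    defaults = STAGE_ACTIVITY_DEFAULTS[stage]
    if genotype == WILD_TYPE:
        return GenotypeSpec(genotype, tuple(1.0 for _ in genes))
    mutated = [g for g in genes if g in genotype]
    if not mutated:
        raise ValueError(
            f"unknown genotype {genotype!r} and no explicit activities supplied"
        )
    acts = tuple(
        defaults[ALLELE_CLASS.get(g, "partial")] if g in mutated else 1.0
        for g in genes
    )
    return GenotypeSpec(genotype, acts)
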