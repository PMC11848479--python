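"""Hypomorph-adapted Modular Response Analysis.

Central fractional differences of mean expression between wild type and one
perturbed genotype per gene are assembled into a response matrix Rp; the
local (direct) interaction matrix is recovered as

    r = -(diag(diag(Rp^-1)))^-1 . Rp^-1

equivalently r_ij = -(Rp^-1)_ij / (Rp^-1)_ii, normalizing the diagonal to
-1 (self-degradation).  The activity fraction gamma of the mutated protein
enters only on the diagonal of Rp, converting the mutant's own transcript
level into an effective protein level.  Uncertainty comes from resampling
cells with replacement within each gene x genotype group.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_core import MUTANT_OF, WILD_TYPE, ExpressionDataset

__all__ = [
    "ResponseMatrix",
    "InteractionMatrix",
    "SingularResponseError",
    "central_fractional_difference",
    "response_matrix",
    "local_response_matrix",
    "bootstrap_mra",
    "summarize_interactions",
]

logger = logging.getLogger(__name__)

DEFAULT_CONDITION_CAP = 1e8


class SingularResponseError(np.linalg.LinAlgError):
    """Response matrix singular or ill-conditioned; carries the estimate."""

    def __init__(self, message: str, condition: float):
        super().__init__(message)
        self.condition = condition


@dataclasses.dataclass(frozen=True)
class ResponseMatrix:
    """Central fractional differences; rows respond, columns perturb."""

    Rp: np.ndarray
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        Rp = np.asarray(self.Rp, dtype=float)
        n = len(self.genes)
        if Rp.shape != (n, n):
            raise ValueError(f"Rp shape {Rp.shape} != ({n}, {n})")
        if np.any(np.abs(Rp) >= 2.0):
            raise ValueError("central fractional differences must lie in (-2, 2)")
        object.__setattr__(self, "Rp", Rp)


@dataclasses.dataclass
class InteractionMatrix:
    """Local response coefficients with bootstrap summaries.

    ``r`` is a representative single-sample matrix (the first bootstrap
    sample, or the only one); ``mean_r`` averages all retained samples.
    ``weak_flags`` marks entries whose percentile CI contains zero.
    """

    r: np.ndarray
    genes: tuple[str, ...]
    bootstrap_samples: np.ndarray | None = None  # (n_kept, n, n)
    mean_r: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    weak_flags: np.ndarray | None = None
    n_skipped: int = 0


def central_fractional_difference(x_wt: float, x_mut: float, f: float = 1.0) -> float:
    """2 (x_mut f - x_wt) / (x_mut f + x_wt), bounded in [-2, 2]."""
    if x_wt < 0 or x_mut < 0:
        raise ValueError("mean expressions must be non-negative")
    if not 0.0 < f <= 1.0:
        raise ValueError(f"activity fraction must be in (0, 1], got {f}")
    num = x_mut * f - x_wt
    den = x_mut * f + x_wt
    if den == 0.0:
        raise ZeroDivisionError(
            "central fractional difference undefined when both levels are zero"
        )
    return 2.0 * num / den


def response_matrix(
    means: pd.DataFrame,
    gammas: Mapping[str, float],
    wt_col: str = WILD_TYPE,
    mutant_cols: Mapping[str, str] | None = None,
) -> ResponseMatrix:
    """Build Rp from a genes x genotypes table of mean expressions.

    ``means`` rows are genes; columns must include the wild type and one
    perturbed genotype per gene (``mutant_cols`` maps gene -> column name,
    defaulting to the standard allele names).  The activity fraction is
    applied only on the diagonal (f_ij = gamma_i if i == j else 1).
    """
    genes = tuple(means.index)
    mutant_cols = dict(mutant_cols or {g: MUTANT_OF.get(g, g) for g in genes})
    if wt_col not in means.columns:
        raise KeyError(f"wild-type column {wt_col!r} missing from means table")
    for g in genes:
        if mutant_cols[g] not in means.columns:
            raise KeyError(f"mutant column {mutant_cols[g]!r} missing for gene {g!r}")
        if not 0.0 < gammas[g] <= 1.0:
            raise ValueError(f"gamma for {g!r} must be in (0, 1]")
    n = len(genes)
    Rp = np.zeros((n, n))
    for i, gi in enumerate(genes):
        x0 = float(means.loc[gi, wt_col])
        for j, gj in enumerate(genes):
            xj = float(means.loc[gi, mutant_cols[gj]])
            f = gammas[gi] if i == j else 1.0
            Rp[i, j] = central_fractional_difference(x0, xj, f)
    return ResponseMatrix(Rp=Rp, genes=genes)


def local_response_matrix(
    rp: ResponseMatrix, condition_cap: float = DEFAULT_CONDITION_CAP
) -> InteractionMatrix:
    """Single-sample interaction matrix r_ij = -(Rp^-1)_ij / (Rp^-1)_ii."""
    Rp = rp.Rp
    cond = np.linalg.cond(Rp)
    if not np.isfinite(cond) or cond > condition_cap:
        raise SingularResponseError(
            f"response matrix ill-conditioned (cond={cond:.3g} > {condition_cap:g})",
            condition=float(cond),
        )
    inv = np.linalg.inv(Rp)
    diag = np.diag(inv)
    if np.any(diag == 0):
        raise SingularResponseError(
            "zero diagonal in Rp^-1; normalization undefined", condition=float(cond)
        )
    r = -inv / diag[:, None]
    return InteractionMatrix(r=r, genes=rp.genes)


def _group_means(
    dataset: ExpressionDataset,
    timepoint: str,
    genotypes: Sequence[str],
) -> dict[tuple[str, str], np.ndarray]:
    groups = {}
    for gene in dataset.genes:
        for gt in genotypes:
            counts = dataset.group_counts(gene, gt, timepoint)
            if counts.size == 0:
                raise ValueError(
                    f"no cells for gene={gene!r} genotype={gt!r} at {timepoint!r}"
                )
            groups[(gene, gt)] = counts.astype(float)
    return groups


def bootstrap_mra(
    dataset: ExpressionDataset,
    timepoint: str,
    activities: Mapping[str, float],
    n_iter: int = 10000,
    seed: int = 0,
    ci_level: float = 0.95,
    mutant_cols: Mapping[str, str] | None = None,
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> InteractionMatrix:
    """Bootstrap distribution of the interaction matrix.

    Each iteration resamples cells with replacement within every
    gene x genotype group, recomputes group means, and runs the MRA step.
    Singular resamples are skipped (and counted), not imputed.  The summary
    matrix is the elementwise average of retained samples with percentile
    confidence intervals.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    genes = dataset.genes
    mutant_cols = dict(mutant_cols or {g: MUTANT_OF.get(g, g) for g in genes})
    genotypes = [WILD_TYPE] + [mutant_cols[g] for g in genes]
    groups = _group_means(dataset, timepoint, genotypes)
    rng = np.random.default_rng(seed)
    samples = []
    n_skipped = 0
    for _ in range(n_iter):
        means = pd.DataFrame(
            {
                gt: [
                    groups[(gene, gt)][
                        rng.integers(0, len(groups[(gene, gt)]), len(groups[(gene, gt)]))
                    ].mean()
                    for gene in genes
                ]
                for gt in genotypes
            },
            index=list(genes),
        )
        try:
            rp = response_matrix(means, activities, mutant_cols=mutant_cols)
            im = local_response_matrix(rp, condition_cap=condition_cap)
        except (SingularResponseError, ZeroDivisionError, ValueError):
            n_skipped += 1
            continue
        samples.append(im.r)
    if not samples:
        raise SingularResponseError(
            f"all {n_iter} bootstrap resamples were singular or invalid",
            condition=float("inf"),
        )
    if n_skipped:
        logger.warning("bootstrap_mra: skipped %d singular resamples", n_skipped)
    arr = np.stack(samples)
    lo = (1.0 - ci_level) / 2.0 * 100.0
    ci_low = np.percentile(arr, lo, axis=0)
    ci_high = np.percentile(arr, 100.0 - lo, axis=0)
    return InteractionMatrix(
        r=arr[0],
        genes=genes,
        bootstrap_samples=arr,
        mean_r=arr.mean(axis=0),
        ci_low=ci_low,
        ci_high=ci_high,
        weak_flags=(ci_low <= 0.0) & (ci_high >= 0.0),
        n_skipped=n_skipped,
    )


def summarize_interactions(
    im: InteractionMatrix, ci_level: float = 0.95
) -> pd.DataFrame:
    """Edge list (off-diagonal entries) with strength, sign and weak flag.

    Strength labels follow the local-response-coefficient reading:
    |r| > 1 amplified, 0 < |r| < 1 attenuated.
    """
    if im.bootstrap_samples is None or im.mean_r is None:
        raise ValueError("summarize_interactions needs bootstrap samples")
    arr = im.bootstrap_samples
    lo = (1.0 - ci_level) / 2.0 * 100.0
    ci_low = np.percentile(arr, lo, axis=0)
    ci_high = np.percentile(arr, 100.0 - lo, axis=0)
    rows = []
    for i, tgt in enumerate(im.genes):
        for j, src in enumerate(im.genes):
            if i == j:
                continue
            strength = float(im.mean_r[i, j])
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "strength": strength,
                    "sign": "activation" if strength > 0 else "repression",
                    "magnitude": "amplified" if abs(strength) > 1 else "attenuated",
                    "ci_low": float(ci_low[i, j]),
                    "ci_high": float(ci_high[i, j]),
                    "weak": bool(ci_low[i, j] <= 0.0 <= ci_high[i, j]),
                }
            )
    return pd.DataFrame(rows)
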