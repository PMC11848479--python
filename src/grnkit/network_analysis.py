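"""Aggregate sampler runs into link statistics and the validated network.

A "link" is a (target, regulator) pair; a link counts as present in a run
when any block-rate parameter realizing it is kept in that run's final fit.
Runs are partitioned by their double-mutant prediction error (kept iff
d <= cutoff), and links absent from at least ``discard_fraction`` of the
kept runs' final fits are deleted from the assembled network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_core import GenotypeSpec
from .grn_ode import genotype_panel
from .sparse_abc import FitTarget, SlingRun, abc_distance

__all__ = [
    "PresenceTable",
    "ValidationPartition",
    "parameter_presence",
    "link_presence",
    "predict_genotype",
    "filter_by_double_mutant",
    "final_network",
    "crosstimepoint_check",
    "report",
]

logger = logging.getLogger(__name__)

DOUBLE_MUTANT_CUTOFF = 2.5


@dataclasses.dataclass
class PresenceTable:
    """Per-parameter and per-link presence percentages across runs."""

    parameters: pd.DataFrame  # name, n_runs, n_kept, percent
    links: pd.DataFrame       # target, regulator, percent, and/or context splits
    n_runs: int


@dataclasses.dataclass
class ValidationPartition:
    """Per-run double-mutant distance and kept/discarded status."""

    distances: list[float]
    kept: list[bool]
    cutoff: float

    def kept_runs(self, runs: Sequence[SlingRun]) -> list[SlingRun]:
        return [r for r, k in zip(runs, self.kept) if k]

    def discarded_runs(self, runs: Sequence[SlingRun]) -> list[SlingRun]:
        return [r for r, k in zip(runs, self.kept) if not k]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": range(len(self.distances)),
                "double_mutant_distance": self.distances,
                "status": ["kept" if k else "discarded" for k in self.kept],
            }
        )


def _links_of_run(run: SlingRun, kept_only: bool = True) -> dict[tuple[str, str], dict]:
    """Links realized by the run's spec, with kept status and logic context."""
    spec = run.spec
    kept = dict(zip(run.param_names, run.kept_mask))
    out: dict[tuple[str, str], dict] = {}
    # walk blocks in canonical order, matching v parameter order
    vi = len(spec.genes)
    for g in spec.genes:
        for blk in spec.blocks.get(g, ()):
            vname = run.param_names[vi]
            vi += 1
            is_and = len(blk) > 1
            for term in blk:
                key = (term.target, term.regulator)
                info = out.setdefault(
                    key, {"kept": False, "and_context": is_and, "params": []}
                )
                info["params"].append(vname)
                if kept[vname]:
                    info["kept"] = True
                info["and_context"] = is_and
    return out


def parameter_presence(runs: Sequence[SlingRun]) -> PresenceTable:
    """Percent of runs whose final fit keeps each parameter / link."""
    if not runs:
        raise ValueError("parameter_presence needs at least one run")
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for run in runs:
        for name, kept in zip(run.param_names, run.kept_mask):
            totals[name] = totals.get(name, 0) + 1
            if kept:
                counts[name] = counts.get(name, 0) + 1
    params = pd.DataFrame(
        [
            {
                "parameter": name,
                "n_runs": totals[name],
                "n_kept": counts.get(name, 0),
                "percent": 100.0 * counts.get(name, 0) / totals[name],
            }
            for name in totals
        ]
    )

    link_counts: dict[tuple[str, str], dict] = {}
    for run in runs:
        for key, info in _links_of_run(run).items():
            rec = link_counts.setdefault(
                key,
                {"n": 0, "kept": 0, "n_and": 0, "kept_and": 0, "n_or": 0, "kept_or": 0},
            )
            rec["n"] += 1
            ctx = "and" if info["and_context"] else "or"
            rec[f"n_{ctx}"] += 1
            if info["kept"]:
                rec["kept"] += 1
                rec[f"kept_{ctx}"] += 1
    links = pd.DataFrame(
        [
            {
                "target": t,
                "regulator": s,
                "n_runs": rec["n"],
                "percent": 100.0 * rec["kept"] / rec["n"],
                "percent_and": (
                    100.0 * rec["kept_and"] / rec["n_and"] if rec["n_and"] else np.nan
                ),
                "percent_or": (
                    100.0 * rec["kept_or"] / rec["n_or"] if rec["n_or"] else np.nan
                ),
            }
            for (t, s), rec in link_counts.items()
        ]
    )
    return PresenceTable(parameters=params, links=links, n_runs=len(runs))


def link_presence(runs: Sequence[SlingRun]) -> pd.DataFrame:
    return parameter_presence(runs).links


def predict_genotype(
    run: SlingRun,
    genotype: GenotypeSpec,
    g0: np.ndarray | None = None,
    summary: str = "median",
) -> np.ndarray:
    """Steady state of the run's parameter summary under one genotype.

    ``summary`` selects the elementwise median of post-burn-in accepted
    states restricted to kept parameters (default) or the final fit.
    """
    if summary == "median":
        params = run.median_parameter_set()
    elif summary == "final":
        params = run.final_parameter_set()
    else:
        raise ValueError(f"unknown summary {summary!r}")
    if g0 is None:
        g0 = np.full(len(run.spec.genes), 10.0)
    S = genotype_panel(run.spec, params, [genotype], np.atleast_2d(g0))
    return S[:, 0]


def filter_by_double_mutant(
    runs: Sequence[SlingRun],
    dm_target: FitTarget,
    dm_genotype: GenotypeSpec,
    cutoff: float = DOUBLE_MUTANT_CUTOFF,
    summary: str = "median",
) -> ValidationPartition:
    """Partition runs by double-mutant prediction error (kept iff d <= cutoff)."""
    if dm_target.m != 1:
        raise ValueError("double-mutant target must have exactly one phenotype column")
    distances, kept = [], []
    for run in runs:
        s = predict_genotype(run, dm_genotype, g0=dm_target.mu[:, 0], summary=summary)
        d = abc_distance(s[:, None], dm_target)
        distances.append(float(d))
        kept.append(d <= cutoff)
    return ValidationPartition(distances=distances, kept=kept, cutoff=cutoff)


def final_network(
    kept_runs: Sequence[SlingRun], discard_fraction: float = 0.90
) -> pd.DataFrame:
    """Links surviving the deletion rule, with sign and logic annotations.

    A link is removed iff it is absent from the final fits of at least
    ``discard_fraction`` of the kept runs (boundary inclusive).
    """
    if not kept_runs:
        raise ValueError("final_network needs a non-empty kept-run set")
    table = parameter_presence(kept_runs)
    rows = []
    sign_votes: dict[tuple[str, str], list[int]] = {}
    for run in kept_runs:
        spec = run.spec
        vals = dict(zip(run.param_names, run.final_fit))
        vi = len(spec.genes)
        for g in spec.genes:
            for blk in spec.blocks.get(g, ()):
                vname = run.param_names[vi]
                vi += 1
                for term in blk:
                    v = vals[vname]
                    if spec.signed:
                        s = 1 if v >= 0 else -1
                    else:
                        s = 1 if term.sign == "activation" else -1
                    sign_votes.setdefault((term.target, term.regulator), []).append(s)
    for _, rec in table.links.iterrows():
        key = (rec["target"], rec["regulator"])
        absent_frac = 1.0 - rec["percent"] / 100.0
        if absent_frac >= discard_fraction:
            continue
        votes = sign_votes.get(key, [1])
        sign = "activation" if np.mean(votes) >= 0 else "repression"
        rows.append(
            {
                "target": rec["target"],
                "regulator": rec["regulator"],
                "sign": sign,
                "presence_percent": rec["percent"],
                "presence_percent_and": rec["percent_and"],
                "presence_percent_or": rec["percent_or"],
            }
        )
    return pd.DataFrame(
        rows, columns=["target", "regulator", "sign", "presence_percent",
                       "presence_percent_and", "presence_percent_or"]
    )


def crosstimepoint_check(
    runs: Sequence[SlingRun],
    other_target: FitTarget,
    genotypes: Sequence[GenotypeSpec],
    summary: str = "median",
) -> tuple[pd.DataFrame, float]:
    """Z-scores of predictions (calibrated elsewhere) against another target.

    Predictions are averaged across runs; returns the per-entry z matrix
    ``(mu_other - s_pred) / sigma_other`` and the aggregate distance (the
    same normalized Euclidean distance evaluated on the averaged panel).
    """
    if not runs:
        raise ValueError("crosstimepoint_check needs at least one run")
    if len(genotypes) != other_target.m:
        raise ValueError("genotype list does not match target phenotypes")
    panels = []
    for run in runs:
        cols = [
            predict_genotype(run, gt, g0=other_target.mu[:, j], summary=summary)
            for j, gt in enumerate(genotypes)
        ]
        panels.append(np.stack(cols, axis=1))
    s_pred = np.mean(panels, axis=0)
    z = (other_target.mu - s_pred) / other_target.sigma
    frame = pd.DataFrame(
        z, index=list(other_target.genes), columns=list(other_target.genotypes)
    )
    return frame, abc_distance(s_pred, other_target)


def report(
    out_dir: str | Path,
    mra_edges: pd.DataFrame | None = None,
    presence: PresenceTable | None = None,
    validation: ValidationPartition | None = None,
    network: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> Path:
    """Write available stage outputs as CSV tables plus a manifest and summary.

    Missing stages are skipped with a warning (an MRA-only bundle is valid).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(out / name, index=False, float_format="%.10g")
        written.append(name)

    if mra_edges is not None:
        save(mra_edges, "mra_edges.csv")
    if presence is not None:
        save(presence.parameters, "parameter_presence.csv")
        save(presence.links, "link_presence.csv")
    if validation is not None:
        save(validation.frame(), "double_mutant_validation.csv")
    if network is not None:
        save(network, "final_network.csv")
        net_json = [
            {
                "source": r["regulator"],
                "target": r["target"],
                "sign": r["sign"],
                "presence_percent": r["presence_percent"],
            }
            for _, r in network.iterrows()
        ]
        (out / "final_network.json").write_text(json.dumps(net_json, indent=2))
        written.append("final_network.json")
    if not written:
        raise ValueError("report needs at least one stage output")
    if mra_edges is None:
        logger.warning("report: no MRA stage output supplied")
    if presence is None:
        logger.warning("report: no sampler stage output supplied; MRA-only bundle")

    doc = {"python": platform.python_version(), "tables": written}
    doc.update(manifest or {})
    (out / "manifest.json").write_text(json.dumps(doc, indent=2, sort_keys=True))

    lines = [f"report bundle: {len(written)} table(s)"]
    for name in written:
        lines.append(f"  - {name}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out
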