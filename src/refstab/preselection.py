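"""Evenness-based preselection of reference candidates from expression arrays.

A good reference candidate is expressed evenly and strongly across all
arrays.  The screen computes, per gene (sum of its probes) and per probe:

* CV — sample standard deviation divided by the mean,
* mean intensity,
* MFC — maximum fold change, max/min over arrays,

and keeps entities satisfying all three strict cutoffs (defaults CV < 0.11,
mean > 1000, MFC < 1.4).  A gene passes the probe-level screen if any (or,
optionally, every) one of its probes passes.  The report gives the
gene-level, probe-level and intersection gene sets.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import IntensityMatrix

__all__ = [
    "Cutoffs",
    "PreselectionReport",
    "aggregate_probes_to_genes",
    "compute_evenness",
    "preselect",
]


@dataclasses.dataclass(frozen=True)
class Cutoffs:
    """Strict evenness cutoffs: CV < cv_max, mean > mean_min, MFC < mfc_max."""

    cv_max: float = 0.11
    mean_min: float = 1000.0
    mfc_max: float = 1.4


@dataclasses.dataclass
class PreselectionReport:
    cutoffs: Cutoffs
    stats: pd.DataFrame  # per entity: level, gene, mean, cv, mfc, pass flags
    gene_level_passed: set[str]
    probe_level_passed: set[str]
    probe_rule: str

    @property
    def both(self) -> set[str]:
        return self.gene_level_passed & self.probe_level_passed

    def counts(self) -> tuple[int, int, int]:
        """(gene-level, probe-level, both) candidate counts."""
        return (
            len(self.gene_level_passed),
            len(self.probe_level_passed),
            len(self.both),
        )

    def to_frame(self) -> pd.DataFrame:
        return self.stats.reset_index()


def aggregate_probes_to_genes(m: IntensityMatrix) -> IntensityMatrix:
    """Gene-level intensities: the sum of all probe intensities per gene."""
    gene_of = pd.Series({p: m.probe_to_gene[p] for p in m.probes})
    summed = m.values.groupby(gene_of).sum()
    summed = summed.loc[sorted(summed.index)]
    return IntensityMatrix(summed, {g: g for g in summed.index})


def compute_evenness(
    m: IntensityMatrix,
    level: Literal["gene", "probe"],
    cutoffs: Cutoffs = Cutoffs(),
) -> pd.DataFrame:
    """Per-entity evenness statistics and strict pass flags.

    CV uses the n−1 sample standard deviation; MFC is max/min over arrays.
    Requires at least two arrays.
    """
    if len(m.arrays) < 2:
        raise ValueError("evenness statistics need >= 2 arrays")
    mat = aggregate_probes_to_genes(m) if level == "gene" else m
    vals = mat.values.to_numpy()
    mean = vals.mean(axis=1)
    cv = vals.std(axis=1, ddof=1) / mean
    mfc = vals.max(axis=1) / vals.min(axis=1)
    stats = pd.DataFrame(
        {
            "level": level,
            "gene": [mat.probe_to_gene[e] for e in mat.probes],
            "mean_intensity": mean,
            "cv": cv,
            "mfc": mfc,
            "cv_ok": cv < cutoffs.cv_max,
            "intensity_ok": mean > cutoffs.mean_min,
            "mfc_ok": mfc < cutoffs.mfc_max,
        },
        index=pd.Index(mat.probes, name="entity"),
    )
    stats["passes"] = stats["cv_ok"] & stats["intensity_ok"] & stats["mfc_ok"]
    return stats


def preselect(
    m: IntensityMatrix,
    cutoffs: Cutoffs = Cutoffs(),
    probe_rule: Literal["any", "all"] = "any",
) -> PreselectionReport:
    """Run the evenness screen at gene and probe level.

    A gene passes gene-level iff its probe-summed intensity row satisfies
    all three strict cutoffs.  Under ``probe_rule='any'`` (default) a gene
    passes probe-level if at least one of its probes passes; under ``'all'``
    every probe must pass.
    """
    if probe_rule not in ("any", "all"):
        raise ValueError(f"unknown probe_rule {probe_rule!r}")
    gene_stats = compute_evenness(m, "gene", cutoffs)
    probe_stats = compute_evenness(m, "probe", cutoffs)
    gene_passed = set(gene_stats.index[gene_stats["passes"]])
    by_gene = probe_stats.groupby("gene")["passes"]
    probe_passed = set(
        (by_gene.any() if probe_rule == "any" else by_gene.all()).pipe(
            lambda s: s.index[s]
        )
    )
    return PreselectionReport(
        cutoffs=cutoffs,
        stats=pd.concat([gene_stats, probe_stats]),
        gene_level_passed=gene_passed,
        probe_level_passed=probe_passed,
        probe_rule=probe_rule,
    )
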