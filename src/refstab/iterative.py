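"""Iterative (circular) comprehensive ranking of reference candidates.

geNorm, NormFinder and the comparative ΔCt score of any one candidate
depend on which other candidates are in the panel, so a single pass over an
uneven panel can be distorted by a few wildly unstable genes.  The circular
assessment repeats the comprehensive ranking, excluding the gene with the
worst (largest) comprehensive score each cycle, until only two genes remain
— the winners.  The full trace of every cycle is retained so that the
stability of the ranking itself can be inspected.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .datamodel import CtMatrix
from .stability import (
    METHODS,
    StabilityResult,
    _argmax_lex,
    _rank_scores,
    bestkeeper,
    ct_to_relative_quantity,
    delta_ct_method,
    genorm,
    normfinder,
    reffinder_aggregate,
)

__all__ = ["IterationCycle", "IterationTrace", "iterative_exclusion", "trace_summary"]


@dataclasses.dataclass
class IterationCycle:
    cycle: int
    surviving: list[str]
    method_scores: pd.DataFrame  # genes x methods (instability scores)
    comprehensive: pd.Series  # per-gene comprehensive instability score
    excluded: str


@dataclasses.dataclass
class IterationTrace:
    cycles: list[IterationCycle]
    final_pair: list[str]
    final_scores: pd.Series  # comprehensive scores in the last cycle
    method_set: list[str]

    def exclusion_order(self) -> list[str]:
        return [c.excluded for c in self.cycles]

    def to_frame(self) -> pd.DataFrame:
        return trace_summary(self)


def _single_cycle(
    cm: CtMatrix,
    methods: list[str],
    efficiencies,
    groups,
    cached_delta_ct: StabilityResult | None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scores of every requested method plus the comprehensive score."""
    results: list[StabilityResult] = []
    needs_rq = {"genorm", "normfinder"} & set(methods)
    rq = ct_to_relative_quantity(cm, efficiencies) if needs_rq else None
    for m in methods:
        if m == "genorm":
            results.append(genorm(rq))
        elif m == "normfinder":
            results.append(normfinder(rq, groups))
        elif m == "delta_ct":
            if cached_delta_ct is not None:
                sub = cached_delta_ct.scores[cm.genes]
                results.append(
                    StabilityResult("delta_ct", sub, _rank_scores(sub),
                                    {"cached": True})
                )
            else:
                results.append(delta_ct_method(cm))
        elif m == "bestkeeper":
            results.append(bestkeeper(cm)[1])
        else:
            raise ValueError(f"unknown method {m!r}")
    score_tab = pd.DataFrame(
        {res.method: res.scores for res in results}
    ).loc[cm.genes]
    if len(results) > 1:
        comp = reffinder_aggregate(results).scores[cm.genes]
    else:
        comp = results[0].scores[cm.genes]
    return score_tab, comp


def iterative_exclusion(
    cm: CtMatrix,
    methods: tuple[str, ...] | list[str] = METHODS,
    efficiencies: Mapping[str, float] | float = 2.0,
    groups: Mapping[str, str] | None = None,
    delta_ct_mode: str = "recompute",
) -> IterationTrace:
    """Run the circular assessment until the final two genes win.

    Each cycle reruns every requested method on the surviving gene set,
    aggregates by geometric mean of ranks (or uses the single method's own
    scores) and excludes the gene with the largest comprehensive score;
    score ties exclude the lexicographically larger gene id.  A G-gene input
    yields exactly G−2 cycles.

    ``delta_ct_mode='cache'`` freezes the ΔCt scores computed on the full
    panel and reuses them in later cycles instead of recomputing on the
    shrunken panel.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("at least one method required")
    if len(cm.genes) < 3:
        raise ValueError("iterative exclusion needs >= 3 genes")
    if delta_ct_mode not in ("recompute", "cache"):
        raise ValueError(f"unknown delta_ct_mode {delta_ct_mode!r}")

    cached = None
    if delta_ct_mode == "cache" and "delta_ct" in methods:
        cached = delta_ct_method(cm)

    surviving = sorted(cm.genes)
    cycles: list[IterationCycle] = []
    current = cm.subset(surviving)
    score_tab, comp = _single_cycle(current, methods, efficiencies, groups, cached)
    n_cycle = 0
    while True:
        n_cycle += 1
        worst = _argmax_lex(comp)
        cycles.append(
            IterationCycle(n_cycle, list(surviving), score_tab, comp, worst)
        )
        surviving = [g for g in surviving if g != worst]
        if len(surviving) == 2:
            break
        current = cm.subset(surviving)
        try:
            score_tab, comp = _single_cycle(
                current, methods, efficiencies, groups, cached
            )
        except ValueError as exc:
            raise ValueError(
                f"method failure at cycle {n_cycle + 1} on gene set "
                f"{surviving}: {exc}"
            ) from exc

    final_scores = cycles[-1].comprehensive[surviving]
    return IterationTrace(cycles, list(surviving), final_scores, methods)


def trace_summary(trace: IterationTrace) -> pd.DataFrame:
    """One row per gene: when it was excluded and its score at that point.

    The final ordering reverses the exclusion order; the two finalists take
    positions 1 and 2 by their comprehensive score in the last cycle (tie ->
    lexicographic id order).
    """
    rows = []
    finalists = sorted(
        trace.final_pair, key=lambda g: (trace.final_scores[g], g)
    )
    for pos, g in enumerate(finalists):
        rows.append(
            {
                "gene": g,
                "exclusion_cycle": "final",
                "score_at_exclusion": float(trace.final_scores[g]),
                "final_order": pos + 1,
            }
        )
    n = len(trace.cycles)
    for i, cyc in enumerate(reversed(trace.cycles)):
        rows.append(
            {
                "gene": cyc.excluded,
                "exclusion_cycle": str(n - i),
                "score_at_exclusion": float(cyc.comprehensive[cyc.excluded]),
                "final_order": 2 + (i + 1),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("final_order")
        .reset_index(drop=True)
    )
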