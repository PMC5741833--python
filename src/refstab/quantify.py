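"""Amplification-efficiency estimation and ΔΔCt relative quantification.

The standard curve fits Ct against log10 relative input over a serial
dilution; the slope s gives the amplification efficiency
E = 10**(−1/s) − 1 (slope −3.32 cycles per 10-fold dilution = 100%).

The ΔΔCt fold change of a target gene between treated and control samples,
normalized by one or more reference genes, is 2**(−ΔΔCt) with
ΔCt = Ct_target − mean Ct_references per replicate unit and
ΔΔCt = ΔCt_treated − mean(ΔCt_control).  The applicability panel evaluates
the same contrast under every candidate reference, exposing how an unstable
reference distorts the apparent fold change of the targets.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CtMatrix, DilutionSeries

__all__ = [
    "EfficiencyFit",
    "FoldChangeResult",
    "fit_efficiency",
    "ddct_fold_change",
    "applicability_panel",
]


@dataclasses.dataclass
class EfficiencyFit:
    """Standard-curve fit: slope in cycles per log10 input; E as a fraction."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def fit_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Least-squares standard curve Ct ~ log10(relative input).

    Relative input at dilution step k is ``dilution_factor**(-k)``.  The
    amplification efficiency is 10**(−1/slope) − 1; a non-negative slope
    (Ct not increasing with dilution) is rejected as an invalid curve.
    """
    x = series.log10_input()
    y = series.cts
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"standard-curve slope {fit.slope:.4f} is non-negative; "
            "Ct must increase with dilution"
        )
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(eff),
    )


@dataclasses.dataclass
class FoldChangeResult:
    """ΔΔCt fold change of one target under one (set of) reference(s)."""

    target: str
    references: list[str]
    ddct: pd.Series  # per treated replicate unit
    fold_change: float  # 2**(-mean ddct)
    sem: float  # SEM of the per-replicate fold changes
    per_replicate_fc: pd.Series = dataclasses.field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": self.target,
                    "references": "+".join(self.references),
                    "fold_change": self.fold_change,
                    "sem": self.sem,
                    "n_replicates": len(self.ddct),
                }
            ]
        )


def _delta_ct(cm: CtMatrix, target: str, references: Sequence[str]) -> np.ndarray:
    """Per-unit ΔCt = Ct_target − mean Ct of the references."""
    missing = [g for g in [target, *references] if g not in cm.genes]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    tgt = cm.values.loc[target].to_numpy()
    ref = cm.values.loc[list(references)].to_numpy().mean(axis=0)
    return tgt - ref


def ddct_fold_change(
    control: CtMatrix,
    treated: CtMatrix,
    target: str,
    references: str | Sequence[str],
    efficiencies: Mapping[str, float] | None = None,
) -> FoldChangeResult:
    """ΔΔCt fold change of ``target`` in treated vs control samples.

    Multiple references are combined by the arithmetic mean of their Ct
    (the geometric mean of their quantities).  With ``efficiencies`` given,
    the efficiency-corrected (Pfaffl-style) ratio
    E_t**(−ΔΔCt_t) / E_r**(−ΔΔCt_r) is computed instead of the plain
    2**(−ΔΔCt); E values are fold amplification per cycle (2.0 = 100%).
    """
    refs = [references] if isinstance(references, str) else list(references)
    if not refs:
        raise ValueError("at least one reference gene required")

    if efficiencies is None:
        d_ctrl = _delta_ct(control, target, refs)
        d_trt = _delta_ct(treated, target, refs)
        ddct = d_trt - d_ctrl.mean()
        per_rep_fc = 2.0 ** (-ddct)
        point = float(2.0 ** (-ddct.mean()))
    else:
        # Pfaffl ratio per treated unit, references combined geometrically
        e_t = float(efficiencies[target])
        t_ctrl = control.values.loc[target].to_numpy()
        t_trt = treated.values.loc[target].to_numpy()
        num = e_t ** (t_ctrl.mean() - t_trt)
        log_den = np.zeros_like(num)
        for r in refs:
            e_r = float(efficiencies[r])
            r_ctrl = control.values.loc[r].to_numpy()
            r_trt = treated.values.loc[r].to_numpy()
            log_den += np.log(e_r) * (r_ctrl.mean() - r_trt)
        ratio = num / np.exp(log_den / len(refs))
        per_rep_fc = ratio
        ddct = -np.log2(ratio)
        point = float(2.0 ** (-ddct.mean()))

    units = treated.units
    sem = (
        float(np.std(per_rep_fc, ddof=1) / np.sqrt(len(per_rep_fc)))
        if len(per_rep_fc) > 1
        else float("nan")
    )
    return FoldChangeResult(
        target=target,
        references=refs,
        ddct=pd.Series(ddct, index=units),
        fold_change=point,
        sem=sem,
        per_replicate_fc=pd.Series(per_rep_fc, index=units),
    )


def applicability_panel(
    control: CtMatrix,
    treated: CtMatrix,
    targets: Sequence[str],
    candidate_refs: Sequence[str],
    reference_order: Sequence[str] | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FoldChangeResult]]:
    """Fold-change grid: every target under every candidate reference.

    Rows are targets, columns candidate references (ordered by
    ``reference_order`` when given, e.g. a stability ranking).  Returns the
    point-estimate grid plus the full per-cell results.
    """
    cols = [r for r in (reference_order or candidate_refs) if r in set(candidate_refs)]
    grid = pd.DataFrame(index=list(targets), columns=cols, dtype=float)
    details: dict[tuple[str, str], FoldChangeResult] = {}
    for t in targets:
        for r in cols:
            res = ddct_fold_change(control, treated, t, r, efficiencies)
            grid.loc[t, r] = res.fold_change
            details[(t, r)] = res
    grid.index.name = "target"
    return grid, details
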