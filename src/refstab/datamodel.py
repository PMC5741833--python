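"""Core data containers for qPCR reference-gene analysis.

The analysis pipeline moves through four kinds of objects:

* :class:`CtDataset` — tidy per-well Ct (quantification-cycle) records with
  the full replicate structure (sample x biological x technical replicate)
  and optional condition labels.
* :class:`CtMatrix` — genes x analysis-units matrix of collapsed Ct values,
  the input every stability algorithm operates on.  An analysis unit is one
  biological replicate of one sample (optionally within one condition).
* :class:`IntensityMatrix` — probes x arrays expression intensities with a
  probe-to-gene map, the input of the evenness preselection screen.
* :class:`DilutionSeries` — Ct readings of a serial dilution, used to
  estimate amplification efficiency from the standard-curve slope.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CT_MAX",
    "CtDataset",
    "CtMatrix",
    "IntensityMatrix",
    "DilutionSeries",
    "collapse_technical_replicates",
]

#: Hard validity ceiling for Ct values (cycles).  A 40-cycle protocol cannot
#: produce crossing points much above 40; 45 leaves margin for extended runs.
CT_MAX = 45.0

_CT_COLUMNS = ["gene", "sample", "bio_rep", "tech_rep", "ct", "condition", "group"]


def _unit_label(sample: str, bio_rep: int, condition: object) -> str:
    if condition is None or (isinstance(condition, float) and math.isnan(condition)):
        return f"{sample}.b{int(bio_rep)}"
    return f"{condition}:{sample}.b{int(bio_rep)}"


@dataclasses.dataclass
class CtDataset:
    """Tidy Ct measurements with replicate structure.

    Parameters
    ----------
    records
        DataFrame with columns ``gene, sample, bio_rep, tech_rep, ct`` and
        optional ``condition`` and ``group``.  ``ct`` is NaN for undetermined
        wells.

    Invariants enforced by :meth:`validate`: each non-missing Ct lies in
    (0, 45]; the (gene, sample, bio_rep, tech_rep, condition) key is unique.
    Genes observed in fewer than two distinct biological units are flagged
    (``unusable_genes``) rather than rejected.
    """

    records: pd.DataFrame
    unusable_genes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in ("condition", "group"):
            if col not in df.columns:
                df[col] = None
        df = df[_CT_COLUMNS]
        df["gene"] = df["gene"].astype(str)
        df["sample"] = df["sample"].astype(str)
        df["bio_rep"] = df["bio_rep"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce").astype(float)
        self.records = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.records
        ct = df["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > CT_MAX) | ~np.isfinite(ct))
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"Ct value {row['ct']} for gene {row['gene']!r} sample "
                f"{row['sample']!r} outside the valid range (0, {CT_MAX}]"
            )
        if (df["bio_rep"] < 1).any() or (df["tech_rep"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        key = ["gene", "sample", "bio_rep", "tech_rep", "condition"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate measurement key "
                f"(gene={first['gene']!r}, sample={first['sample']!r}, "
                f"bio_rep={first['bio_rep']}, tech_rep={first['tech_rep']}, "
                f"condition={first['condition']!r})"
            )
        # genes must cover >= 2 biological units to be usable downstream
        units = df.assign(
            unit=[
                _unit_label(s, b, c)
                for s, b, c in zip(df["sample"], df["bio_rep"], df["condition"])
            ]
        )
        n_units = units[units["ct"].notna()].groupby("gene")["unit"].nunique()
        self.unusable_genes = sorted(
            set(df["gene"]) - set(n_units[n_units >= 2].index)
        )

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def conditions(self) -> list[str]:
        vals = self.records["condition"].dropna().unique()
        return sorted(str(v) for v in vals)

    def subset_conditions(self, conditions: list[str]) -> "CtDataset":
        mask = self.records["condition"].isin(conditions)
        return CtDataset(self.records[mask].reset_index(drop=True))

    def n_missing(self) -> int:
        return int(self.records["ct"].isna().sum())


@dataclasses.dataclass
class CtMatrix:
    """Collapsed Ct values: one row per gene, one column per analysis unit."""

    values: pd.DataFrame  # genes x units
    group_of_unit: dict[str, str] | None = None
    collapse_report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    def validate(self, max_missing_frac: float = 0.0) -> None:
        vals = self.values.to_numpy()
        if vals.size == 0:
            raise ValueError("empty Ct matrix")
        finite = np.isfinite(vals)
        missing = np.isnan(vals)
        if not (finite | missing).all():
            raise ValueError("Ct matrix contains non-finite, non-NaN values")
        if missing.all(axis=1).any():
            gene = self.values.index[missing.all(axis=1)][0]
            raise ValueError(f"gene {gene!r} has no observed values")
        frac = missing.mean()
        if frac > max_missing_frac:
            raise ValueError(
                f"missing fraction {frac:.4f} exceeds allowed {max_missing_frac}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def units(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: list[str]) -> "CtMatrix":
        return CtMatrix(self.values.loc[genes], self.group_of_unit)

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()


def collapse_technical_replicates(
    ds: CtDataset,
    method: Literal["mean", "median"] = "mean",
    missing_policy: Literal["drop_gene", "keep", "error"] = "drop_gene",
) -> CtMatrix:
    """Collapse technical replicates to one Ct per biological unit.

    Each (sample, bio_rep[, condition]) combination becomes one analysis
    unit; the cell value is the mean (default) or median of the non-missing
    technical replicates.  A cell with no observed replicate is missing;
    under the default ``drop_gene`` policy any gene with a missing cell is
    dropped (with a warning) so that the result is a complete matrix, which
    is what the stability algorithms require.

    The per-gene missingness report is attached as ``collapse_report``.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    df = ds.records.copy()
    df["unit"] = [
        _unit_label(s, b, c)
        for s, b, c in zip(df["sample"], df["bio_rep"], df["condition"])
    ]
    agg = df.groupby(["gene", "unit"])["ct"].agg(method)
    wide = agg.unstack("unit")
    # preserve first-appearance order of units, genes sorted for determinism
    unit_order = list(dict.fromkeys(df["unit"]))
    wide = wide.loc[sorted(wide.index), unit_order]

    n_missing_cells = wide.isna().sum(axis=1)
    report = pd.DataFrame(
        {
            "gene": wide.index,
            "n_units": wide.shape[1],
            "n_missing_cells": n_missing_cells.to_numpy(),
            "dropped": False,
        }
    ).set_index("gene")

    incomplete = list(wide.index[n_missing_cells > 0])
    if incomplete:
        if missing_policy == "error":
            raise ValueError(
                f"genes with missing collapsed cells: {incomplete}"
            )
        if missing_policy == "drop_gene":
            warnings.warn(
                f"dropping {len(incomplete)} gene(s) with missing collapsed "
                f"cells: {incomplete}",
                stacklevel=2,
            )
            report.loc[incomplete, "dropped"] = True
            wide = wide.drop(index=incomplete)
    if wide.shape[0] == 0:
        raise ValueError("no genes left after applying the missing-data policy")

    group_map: dict[str, str] | None = None
    cond = df.dropna(subset=["condition"]) if df["condition"].notna().any() else None
    if cond is not None:
        group_map = dict(
            cond.groupby("unit")["condition"].first().astype(str)
        )
    elif df["group"].notna().any():
        group_map = dict(df.dropna(subset=["group"]).groupby("unit")["group"].first())

    return CtMatrix(wide, group_of_unit=group_map, collapse_report=report)


@dataclasses.dataclass
class IntensityMatrix:
    """Probe-level expression intensities with a probe-to-gene map.

    Intensities must be strictly positive: the evenness screen divides by
    means and minima, and log transforms are applied downstream.
    """

    values: pd.DataFrame  # probes x arrays
    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.probe_to_gene = {str(k): str(v) for k, v in dict(self.probe_to_gene).items()}
        self.validate()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        if vals.size == 0:
            raise ValueError("empty intensity matrix")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("intensities must be finite and strictly positive")
        unmapped = [p for p in self.values.index if p not in self.probe_to_gene]
        if unmapped:
            raise ValueError(f"probes without gene annotation: {unmapped}")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.probe_to_gene[p] for p in self.values.index))


@dataclasses.dataclass
class DilutionSeries:
    """Ct readings of a serial dilution (standard curve input).

    ``points`` maps dilution step k (0 = undiluted top of the series) to the
    measured Ct; relative input at step k is ``dilution_factor ** -k``.
    """

    points: list[tuple[int, float]]
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        steps = [int(s) for s, _ in self.points]
        if len(set(steps)) < 3:
            raise ValueError("a dilution series needs >= 3 distinct steps")
        if any(s < 0 for s in steps):
            raise ValueError("dilution steps must be >= 0")
        if not all(np.isfinite(ct) for _, ct in self.points):
            raise ValueError("Ct values must be finite")

    @property
    def steps(self) -> np.ndarray:
        return np.array([s for s, _ in self.points], dtype=float)

    @property
    def cts(self) -> np.ndarray:
        return np.array([ct for _, ct in self.points], dtype=float)

    def log10_input(self) -> np.ndarray:
        """log10 of relative template input at each point."""
        return -self.steps * math.log10(self.dilution_factor)
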