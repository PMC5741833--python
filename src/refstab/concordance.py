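"""Between-method concordance of stability rankings.

Each method's per-gene *stability* score is the reciprocal of its
instability score (zero instability is capped rather than dropped, so a
perfectly stable synthetic gene still enters the correlations).  Array-based
stability variants mirror the expression-evenness screen:

* ``ArrayG``   — 1/CV of the gene-level (probe-summed) intensities,
* ``ArrayPCV`` — 1/CV of the gene's most even probe (minimum CV),
* ``ArrayPInt``— 1/CV of the gene's strongest probe (maximum mean intensity).

Concordance between methods is the Pearson correlation of stability scores
over the genes shared by each pair.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .datamodel import IntensityMatrix
from .preselection import compute_evenness
from .stability import StabilityResult

__all__ = [
    "RECIPROCAL_CAP_EPS",
    "ConcordanceMatrix",
    "stability_scores",
    "array_stability_scores",
    "correlate_methods",
]

#: Zero instability maps to 1/RECIPROCAL_CAP_EPS instead of infinity.
RECIPROCAL_CAP_EPS = 1e-6


@dataclasses.dataclass
class ConcordanceMatrix:
    r: pd.DataFrame  # methods x methods Pearson r (NaN where undefined)
    n: pd.DataFrame  # shared-gene count per pair

    def to_frame(self) -> pd.DataFrame:
        return self.r


def stability_scores(
    result: StabilityResult | pd.Series, eps: float = RECIPROCAL_CAP_EPS
) -> pd.Series:
    """Reciprocal of the instability score; zero capped at 1/eps."""
    scores = result.scores if isinstance(result, StabilityResult) else result
    scores = scores.astype(float)
    if (scores < 0).any():
        bad = scores[scores < 0].index[0]
        raise ValueError(f"negative instability score for gene {bad!r}")
    return 1.0 / scores.clip(lower=eps)


def array_stability_scores(
    m: IntensityMatrix, eps: float = RECIPROCAL_CAP_EPS
) -> dict[str, pd.Series]:
    """The three array-based stability variants (reciprocal CV), per gene."""
    gene_stats = compute_evenness(m, "gene")
    probe_stats = compute_evenness(m, "probe")
    array_g = stability_scores(gene_stats["cv"], eps)
    array_g.index = gene_stats["gene"]

    by_gene = probe_stats.groupby("gene")
    pcv = by_gene["cv"].min()
    # per gene, the CV of the probe with the largest mean intensity
    best_int = probe_stats.loc[
        by_gene["mean_intensity"].idxmax().to_numpy(), ["gene", "cv"]
    ].set_index("gene")["cv"]
    return {
        "ArrayG": array_g,
        "ArrayPCV": stability_scores(pcv, eps),
        "ArrayPInt": stability_scores(best_int, eps),
    }


def correlate_methods(
    scores: Mapping[str, pd.Series], min_shared: int = 3
) -> ConcordanceMatrix:
    """Pairwise Pearson r of per-gene stability scores.

    Correlations are computed on the intersection of each pair's gene sets;
    pairs sharing fewer than ``min_shared`` genes (or with a zero-variance
    member) are reported as NaN.  The matrix is symmetric with unit
    diagonal.
    """
    names = list(scores)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        n.loc[name, name] = len(scores[name])
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = scores[a].index.intersection(scores[b].index)
            n.loc[a, b] = n.loc[b, a] = len(shared)
            if len(shared) < min_shared:
                val = np.nan
            else:
                x = scores[a][shared].to_numpy(dtype=float)
                y = scores[b][shared].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    val = np.nan
                else:
                    val = float(np.corrcoef(x, y)[0, 1])
            r.loc[a, b] = r.loc[b, a] = val
    return ConcordanceMatrix(r, n)
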