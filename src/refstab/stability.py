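"""The four reference-gene stability algorithms and their comprehensive ranking.

All four methods consume a complete genes x units Ct matrix (technical
replicates already collapsed) and produce a per-gene *instability score* —
the smaller, the more stable — plus ranks (1 = most stable, ties averaged):

* **geNorm** — a gene's M value is the mean, over all partner genes, of the
  standard deviation across units of the log2 expression ratio to that
  partner.  The procedure is stepwise: the gene with the largest M is
  removed and M is recomputed on the remainder, until two genes are left.
  The companion pairwise-variation statistic V(n/n+1) guides how many
  reference genes are needed.
* **NormFinder** (ungrouped and grouped) — a variance-decomposition model on
  sample-centered log expression; grouped mode additionally penalizes
  systematic between-group deviation, with shrinkage of the group effects.
* **comparative ΔCt** — the mean, over partner genes, of the SD across units
  of the pairwise Ct difference.
* **BestKeeper** — descriptive dispersion of raw Ct (mean absolute deviation
  about the arithmetic mean) plus the correlation of each gene with the
  BestKeeper index (per-unit geometric mean Ct).

The comprehensive ("RefFinder-style") score of a gene is the geometric mean
of its four ranks.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CtMatrix

__all__ = [
    "RelativeQuantityMatrix",
    "StabilityResult",
    "BestKeeperStats",
    "ct_to_relative_quantity",
    "genorm",
    "genorm_pairwise_variation",
    "normfinder",
    "delta_ct_method",
    "bestkeeper",
    "reffinder_aggregate",
    "run_all_methods",
]

METHODS = ("genorm", "normfinder", "delta_ct", "bestkeeper")


@dataclasses.dataclass
class RelativeQuantityMatrix:
    """Relative quantities q = E**(minCt - Ct), one row per gene.

    Each gene's most abundant unit (lowest Ct) has q = 1; all quantities are
    in (0, 1].  E is the per-gene amplification factor per cycle (2.0 at
    100% efficiency).
    """

    values: pd.DataFrame  # genes x units, all positive, row max == 1
    efficiencies: pd.Series  # per-gene fold amplification per cycle

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def units(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> np.ndarray:
        return np.log2(self.values.to_numpy())

    def subset(self, genes: list[str]) -> "RelativeQuantityMatrix":
        return RelativeQuantityMatrix(self.values.loc[genes], self.efficiencies[genes])


@dataclasses.dataclass
class StabilityResult:
    """Per-gene instability scores and ranks for one method."""

    method: str
    scores: pd.Series  # instability, smaller = more stable
    ranks: pd.Series  # 1 = most stable; ties -> average rank
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.ranks = self.ranks.astype(float).reindex(self.scores.index)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return (
            pd.DataFrame(
                {"gene": self.scores.index, "score": self.scores.to_numpy(),
                 "rank": self.ranks.to_numpy(), "method": self.method}
            )
            .sort_values(["rank", "gene"])
            .reset_index(drop=True)
        )


@dataclasses.dataclass
class BestKeeperStats:
    """BestKeeper descriptive statistics per gene plus the per-unit index."""

    table: pd.DataFrame  # per-gene descriptive stats
    index: pd.Series  # per-unit geometric mean Ct over genes

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def _rank_scores(scores: pd.Series) -> pd.Series:
    """Ascending average ranks: lowest instability -> rank 1."""
    return pd.Series(
        stats.rankdata(scores.to_numpy(), method="average"),
        index=scores.index, dtype=float,
    )


def _require_complete(cm: CtMatrix) -> np.ndarray:
    vals = cm.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(
            "Ct matrix has missing cells; collapse with "
            "missing_policy='drop_gene' or resolve missing data first"
        )
    return vals


def ct_to_relative_quantity(
    cm: CtMatrix, efficiencies: Mapping[str, float] | float = 2.0
) -> RelativeQuantityMatrix:
    """Transform Ct values to relative quantities q = E**(minCt − Ct).

    ``efficiencies`` is a single fold-amplification factor or a per-gene
    map; 2.0 corresponds to 100% amplification efficiency.  Each value must
    lie in (1, 2.2].
    """
    vals = _require_complete(cm)
    genes = cm.genes
    if isinstance(efficiencies, Mapping):
        eff = pd.Series({g: float(efficiencies[g]) for g in genes}, dtype=float)
    else:
        eff = pd.Series(float(efficiencies), index=genes, dtype=float)
    if ((eff <= 1.0) | (eff > 2.2)).any():
        bad = eff[(eff <= 1.0) | (eff > 2.2)].index[0]
        raise ValueError(f"efficiency for {bad!r} outside (1, 2.2]")
    delta = vals.min(axis=1, keepdims=True) - vals
    q = eff.to_numpy()[:, None] ** delta
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=genes, columns=cm.units), eff
    )


def _pairwise_v(log_q: np.ndarray) -> np.ndarray:
    """geNorm pairwise variation: V[j, k] = SD over units of log2(q_j/q_k)."""
    diffs = log_q[:, None, :] - log_q[None, :, :]
    return diffs.std(axis=2, ddof=1)


def _argmax_lex(scores: pd.Series) -> str:
    """Index of the maximal score; ties -> lexicographically largest id."""
    m = scores.max()
    return max(g for g in scores.index if scores[g] == m)


def genorm(rq: RelativeQuantityMatrix, stepwise: bool = True) -> StabilityResult:
    """geNorm M-value ranking.

    In the default stepwise mode the mean pairwise-variation M of every
    surviving gene is recorded and the gene with the largest M is excluded,
    until two genes remain.  A gene's reported score is its M at the step of
    its exclusion; the final pair is scored with their mutual pair SD and
    shares rank 1.5.  Ties in the argmax are broken toward the
    lexicographically larger id.

    With ``stepwise=False`` the reported score is simply each gene's
    full-panel M (no exclusion), ranked ascending; at 100% efficiency this
    M equals the comparative-deltaCt score exactly.
    """
    genes = rq.genes
    if len(genes) < 3:
        raise ValueError("geNorm needs >= 3 genes")
    if len(rq.units) < 2:
        raise ValueError("geNorm needs >= 2 units")
    log_q = rq.log2()

    if not stepwise:
        v = _pairwise_v(log_q)
        m = pd.Series(v.sum(axis=1) / (len(genes) - 1), index=genes)
        return StabilityResult("genorm", m, _rank_scores(m), {"stepwise": False})

    surviving = list(genes)
    scores: dict[str, float] = {}
    exclusion_order: list[str] = []
    m_trace: list[pd.Series] = []
    while len(surviving) > 2:
        idx = [genes.index(g) for g in surviving]
        v = _pairwise_v(log_q[idx])
        m = pd.Series(v.sum(axis=1) / (len(surviving) - 1), index=surviving)
        m_trace.append(m)
        worst = _argmax_lex(m)
        scores[worst] = float(m[worst])
        exclusion_order.append(worst)
        surviving.remove(worst)
    # final pair: mutual pair SD, shared rank 1.5
    idx = [genes.index(g) for g in surviving]
    pair_sd = float(_pairwise_v(log_q[idx])[0, 1])
    for g in surviving:
        scores[g] = pair_sd

    ranks = {g: 1.5 for g in surviving}
    for pos, g in enumerate(reversed(exclusion_order)):
        ranks[g] = 3.0 + pos
    return StabilityResult(
        "genorm",
        pd.Series(scores).reindex(genes),
        pd.Series(ranks).reindex(genes),
        metadata={
            "exclusion_order": exclusion_order,
            "final_pair": sorted(surviving),
            "m_trace": [t.to_dict() for t in m_trace],
        },
    )


def genorm_pairwise_variation(
    rq: RelativeQuantityMatrix, ranked_genes: list[str]
) -> pd.Series:
    """geNorm V(n/n+1): SD over units of log2(NF_n / NF_{n+1}).

    NF_n(u) is the geometric mean quantity of the n best-ranked genes at
    unit u.  Low V(n/n+1) means adding the (n+1)-th gene barely changes the
    normalization factor, so n genes suffice.
    """
    g = len(ranked_genes)
    if g < 3:
        raise ValueError("pairwise variation needs >= 3 ranked genes")
    log_q = rq.subset(ranked_genes).log2()
    out = {}
    for n in range(2, g):
        nf_n = log_q[:n].mean(axis=0)
        nf_n1 = log_q[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, name="pairwise_variation")


def normfinder(
    rq: RelativeQuantityMatrix,
    groups: Mapping[str, str] | None = None,
) -> StabilityResult:
    """NormFinder model-based stability value.

    Works on sample-centered log2 quantities z_gu = y_gu − mean_g'(y_g'u),
    which removes the per-unit loading component.  Without groups the score
    is simply the SD of z over units.  With groups the score combines the
    intragroup variation with the shrunken absolute intergroup deviation of
    each gene, so a gene that shifts systematically between conditions is
    penalized even if its within-group variance is small.
    """
    genes = rq.genes
    if len(genes) < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    y = rq.log2()
    z = y - y.mean(axis=0, keepdims=True)

    if groups is None:
        scores = pd.Series(z.std(axis=1, ddof=1), index=genes)
        meta = {"mode": "ungrouped"}
    else:
        labels = np.array([str(groups[u]) for u in rq.units])
        uniq = sorted(set(labels))
        if len(uniq) < 2:
            raise ValueError("grouped NormFinder needs >= 2 groups")
        counts = {g: int((labels == g).sum()) for g in uniq}
        if min(counts.values()) < 2:
            small = min(counts, key=counts.get)
            raise ValueError(f"group {small!r} has fewer than 2 units")
        n_j = np.array([counts[g] for g in uniq], dtype=float)
        group_mean = np.stack(
            [z[:, labels == g].mean(axis=1) for g in uniq], axis=1
        )  # genes x groups
        s2 = np.stack(
            [z[:, labels == g].var(axis=1, ddof=1) for g in uniq], axis=1
        )
        d = group_mean - z.mean(axis=1, keepdims=True)
        gamma2 = np.maximum(
            0.0, d.var(axis=1, ddof=1) - (s2 / n_j).mean(axis=1)
        )[:, None]
        denom = gamma2 + s2 / n_j
        with np.errstate(invalid="ignore", divide="ignore"):
            d_shrunk = np.where(denom > 0, d * gamma2 / denom, 0.0)
            var_term = np.where(denom > 0, gamma2 * (s2 / n_j) / denom, 0.0)
        stab = (np.abs(d_shrunk) + np.sqrt(var_term)).mean(axis=1)
        scores = pd.Series(stab, index=genes)
        meta = {"mode": "grouped", "groups": counts}
    return StabilityResult("normfinder", scores, _rank_scores(scores), meta)


def delta_ct_method(cm: CtMatrix) -> StabilityResult:
    """Comparative ΔCt stability: mean over partners of pairwise ΔCt SD.

    For genes j, k the SD across units of (Ct_j − Ct_k) measures how stable
    the pair's ratio is; a gene's score averages this SD over all partners.
    """
    vals = _require_complete(cm)
    if len(cm.genes) < 3:
        raise ValueError("the comparative deltaCt method needs >= 3 genes")
    if len(cm.units) < 3:
        raise ValueError("the comparative deltaCt method needs >= 3 units")
    sd = _pairwise_v(vals)  # SD of pairwise Ct differences (log-free identity)
    scores = pd.Series(sd.sum(axis=1) / (len(cm.genes) - 1), index=cm.genes)
    return StabilityResult("delta_ct", scores, _rank_scores(scores))


def bestkeeper(
    cm: CtMatrix,
    dispersion: Literal["mad", "sd"] = "mad",
) -> tuple[BestKeeperStats, StabilityResult]:
    """BestKeeper descriptive dispersion of raw Ct values.

    The canonical dispersion ("S.D. (± CP)") is the mean absolute deviation
    of a gene's Ct about its arithmetic mean; ``dispersion='sd'`` switches to
    the sample SD for sensitivity analysis.  Genes with dispersion > 1 cycle
    are flagged inconsistent.  The BestKeeper index is the per-unit
    geometric mean Ct over all genes; each gene's Pearson correlation with
    the index is reported descriptively (NaN for zero-dispersion genes).
    Unlike the ratio-based methods, BestKeeper is sensitive to per-unit
    loading shifts, because it works on raw Ct.
    """
    vals = _require_complete(cm)
    if len(cm.units) < 2:
        raise ValueError("BestKeeper needs >= 2 units")
    if (vals <= 0).any():
        raise ValueError("BestKeeper requires positive Ct values")
    am = vals.mean(axis=1)
    if dispersion == "mad":
        disp = np.abs(vals - am[:, None]).mean(axis=1)
    elif dispersion == "sd":
        disp = vals.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown dispersion {dispersion!r}")
    gm = stats.gmean(vals, axis=1)
    index = stats.gmean(vals, axis=0)  # per-unit geometric mean over genes

    r = np.full(len(cm.genes), np.nan)
    if np.std(index) > 0:
        for i in range(len(cm.genes)):
            if vals[i].std() > 0:
                r[i] = np.corrcoef(vals[i], index)[0, 1]
    table = pd.DataFrame(
        {
            "geo_mean_ct": gm,
            "arith_mean_ct": am,
            "min_ct": vals.min(axis=1),
            "max_ct": vals.max(axis=1),
            "dispersion": disp,
            "cv_percent": 100.0 * disp / am,
            "consistent": disp <= 1.0,
            "r_vs_index": r,
        },
        index=pd.Index(cm.genes, name="gene"),
    )
    scores = pd.Series(disp, index=cm.genes)
    result = StabilityResult(
        "bestkeeper", scores, _rank_scores(scores), {"dispersion": dispersion}
    )
    return BestKeeperStats(table, pd.Series(index, index=cm.units)), result


def reffinder_aggregate(results: list[StabilityResult]) -> StabilityResult:
    """Comprehensive score: geometric mean of each gene's per-method ranks.

    All input results must cover the same gene set.  The comprehensive
    instability score of a gene ranked r_1..r_m by the m methods is
    (r_1 · ... · r_m)**(1/m); genes are re-ranked by this score (ties
    averaged).
    """
    if not results:
        raise ValueError("no stability results to aggregate")
    gene_set = set(results[0].genes)
    for res in results[1:]:
        if set(res.genes) != gene_set:
            raise ValueError(
                f"gene-set mismatch between {results[0].method!r} and "
                f"{res.method!r}: "
                f"{sorted(gene_set ^ set(res.genes))}"
            )
    genes = sorted(gene_set)
    rank_mat = np.stack([res.ranks.reindex(genes).to_numpy() for res in results])
    scores = pd.Series(
        np.exp(np.log(rank_mat).mean(axis=0)), index=genes, dtype=float
    )
    return StabilityResult(
        "reffinder",
        scores,
        _rank_scores(scores),
        metadata={"methods": [res.method for res in results]},
    )


def run_all_methods(
    cm: CtMatrix,
    efficiencies: Mapping[str, float] | float = 2.0,
    groups: Mapping[str, str] | None = None,
) -> dict[str, StabilityResult]:
    """Run all four methods plus the comprehensive aggregation on one matrix."""
    rq = ct_to_relative_quantity(cm, efficiencies)
    out = {
        "genorm": genorm(rq),
        "normfinder": normfinder(rq, groups),
        "delta_ct": delta_ct_method(cm),
        "bestkeeper": bestkeeper(cm)[1],
    }
    out["reffinder"] = reffinder_aggregate([out[m] for m in METHODS])
    return out
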