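"""Independent brute-force reference implementations of every statistic.

Everything here is written with plain Python loops and the ``statistics``
module — deliberately no shared code (and no numpy vectorization) with the
package, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
import statistics


def sd(xs) -> float:
    return statistics.stdev(xs)  # n-1 denominator


def brute_relative_quantity(ct_rows: dict[str, list[float]], eff: float = 2.0):
    q = {}
    for g, row in ct_rows.items():
        m = min(row)
        q[g] = [eff ** (m - c) for c in row]
    return q


def brute_pairwise_sd_log2(qa: list[float], qb: list[float]) -> float:
    ratios = [math.log2(a / b) for a, b in zip(qa, qb)]
    return sd(ratios)


def brute_genorm(ct_rows: dict[str, list[float]], eff: float = 2.0):
    """Full stepwise geNorm: scores, ranks and exclusion order."""
    q = brute_relative_quantity(ct_rows, eff)
    surviving = sorted(ct_rows)
    scores, ranks = {}, {}
    exclusion = []
    while len(surviving) > 2:
        m_vals = {}
        for g in surviving:
            total = 0.0
            for h in surviving:
                if h != g:
                    total += brute_pairwise_sd_log2(q[g], q[h])
            m_vals[g] = total / (len(surviving) - 1)
        worst_score = max(m_vals.values())
        worst = max(g for g in surviving if m_vals[g] == worst_score)
        scores[worst] = m_vals[worst]
        exclusion.append(worst)
        surviving.remove(worst)
    pair_sd = brute_pairwise_sd_log2(q[surviving[0]], q[surviving[1]])
    for g in surviving:
        scores[g] = pair_sd
        ranks[g] = 1.5
    for i, g in enumerate(reversed(exclusion)):
        ranks[g] = 3.0 + i
    return scores, ranks, exclusion


def brute_pairwise_variation(ct_rows, ranked, eff: float = 2.0):
    """V(n/n+1) from the geometric-mean normalization factors."""
    q = brute_relative_quantity(ct_rows, eff)
    n_units = len(next(iter(ct_rows.values())))
    out = {}
    for n in range(2, len(ranked)):
        diffs = []
        for u in range(n_units):
            nf_n = math.prod(q[g][u] for g in ranked[:n]) ** (1.0 / n)
            nf_n1 = math.prod(q[g][u] for g in ranked[: n + 1]) ** (1.0 / (n + 1))
            diffs.append(math.log2(nf_n / nf_n1))
        out[f"V{n}/{n + 1}"] = sd(diffs)
    return out


def brute_delta_ct(ct_rows: dict[str, list[float]]):
    genes = sorted(ct_rows)
    scores = {}
    for g in genes:
        acc = 0.0
        for h in genes:
            if h != g:
                diffs = [a - b for a, b in zip(ct_rows[g], ct_rows[h])]
                acc += sd(diffs)
        scores[g] = acc / (len(genes) - 1)
    return scores


def brute_bestkeeper(ct_rows: dict[str, list[float]]):
    """Dispersion = mean absolute deviation about the arithmetic mean."""
    scores = {}
    for g, row in ct_rows.items():
        am = sum(row) / len(row)
        scores[g] = sum(abs(c - am) for c in row) / len(row)
    return scores


def brute_normfinder_ungrouped(ct_rows: dict[str, list[float]], eff: float = 2.0):
    q = brute_relative_quantity(ct_rows, eff)
    genes = sorted(ct_rows)
    n_units = len(next(iter(ct_rows.values())))
    y = {g: [math.log2(v) for v in q[g]] for g in genes}
    col_mean = [
        sum(y[g][u] for g in genes) / len(genes) for u in range(n_units)
    ]
    return {g: sd([y[g][u] - col_mean[u] for u in range(n_units)]) for g in genes}


def brute_normfinder_grouped(
    ct_rows: dict[str, list[float]], group_of_unit: list[str], eff: float = 2.0
):
    q = brute_relative_quantity(ct_rows, eff)
    genes = sorted(ct_rows)
    n_units = len(group_of_unit)
    y = {g: [math.log2(v) for v in q[g]] for g in genes}
    col_mean = [sum(y[g][u] for g in genes) / len(genes) for u in range(n_units)]
    z = {g: [y[g][u] - col_mean[u] for u in range(n_units)] for g in genes}
    groups = sorted(set(group_of_unit))
    scores = {}
    for g in genes:
        overall = sum(z[g]) / n_units
        d, s2, n_j = [], [], []
        for grp in groups:
            vals = [z[g][u] for u in range(n_units) if group_of_unit[u] == grp]
            n_j.append(len(vals))
            d.append(sum(vals) / len(vals) - overall)
            s2.append(statistics.variance(vals))
        mean_noise = sum(s / n for s, n in zip(s2, n_j)) / len(groups)
        gamma2 = max(0.0, statistics.variance(d) - mean_noise)
        total = 0.0
        for dj, sj, nj in zip(d, s2, n_j):
            denom = gamma2 + sj / nj
            if denom > 0:
                dt = dj * gamma2 / denom
                var_term = gamma2 * (sj / nj) / denom
            else:
                dt, var_term = 0.0, 0.0
            total += abs(dt) + math.sqrt(var_term)
        scores[g] = total / len(groups)
    return scores


def brute_rank(scores: dict[str, float]) -> dict[str, float]:
    """Ascending average ranks."""
    genes = sorted(scores)
    ranks = {}
    for g in genes:
        less = sum(1 for h in genes if scores[h] < scores[g])
        equal = sum(1 for h in genes if scores[h] == scores[g])
        ranks[g] = less + (equal + 1) / 2.0
    return ranks


def brute_reffinder(rank_sets: list[dict[str, float]]):
    genes = sorted(rank_sets[0])
    m = len(rank_sets)
    return {
        g: math.prod(rs[g] for rs in rank_sets) ** (1.0 / m) for g in genes
    }
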