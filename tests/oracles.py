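"""Independent brute-force oracles, deliberately implemented apart from the engine.

Everything here favours clarity over speed: explicit Python loops, direct
formula transcription, naive O(n^3) agglomeration, exhaustive enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import sqrt


def ssgsea_es_oracle(values, genes, set_genes, weight_exponent):
    """Integrated running-sum ES for one sample via direct summation.

    values: per-gene expression for one sample, aligned with `genes`.
    Ranks descend; ties broken by input order; rank weight of the j-th gene
    in the walk (0-based) is N - j. ES is the sum of the running statistic.
    """
    n = len(genes)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    in_set = [genes[i] in set(set_genes) for i in order]
    m = sum(in_set)
    weights = [(n - j) ** weight_exponent if in_set[j] else 0.0 for j in range(n)]
    denom = sum(weights)
    running = 0.0
    es = 0.0
    for j in range(n):
        if in_set[j]:
            running += weights[j] / denom
        else:
            running -= 1.0 / (n - m)
        es += running
    return es


def average_ranks(values):
    """Average ranks (1-based) with explicit tie handling."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho: Pearson formula applied to average ranks, by hand."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / sqrt(vx * vy)


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up applied literally to the definition."""
    m = len(pvalues)
    indexed = sorted(enumerate(pvalues), key=lambda t: t[1])
    scaled = [p * m / (i + 1) for i, (_, p) in enumerate(indexed)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for (orig, _), adj in zip(indexed, scaled):
        out[orig] = min(adj, 1.0)
    return out


def gsea_es_oracle(scores, hit_indices):
    """Max-deviation weighted KS statistic, direct transcription."""
    n = len(scores)
    hits = set(hit_indices)
    m = len(hits)
    denom = sum(abs(scores[i]) for i in hits)
    p_hit = p_miss = 0.0
    best = 0.0
    for i in range(n):
        if i in hits:
            p_hit += abs(scores[i]) / denom
        else:
            p_miss += 1.0 / (n - m)
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


def gsea_exhaustive(scores, hit_indices):
    """Observed ES plus the full null over every same-size subset, with the
    engine's documented two-tailed +1-smoothed p formula."""
    n = len(scores)
    m = len(hit_indices)
    es = gsea_es_oracle(scores, hit_indices)
    null = [gsea_es_oracle(scores, subset) for subset in combinations(range(n), m)]
    sign = 1.0 if es >= 0 else -1.0
    same = [v for v in null if (1.0 if v > 0 else -1.0) == sign]
    k = sum(1 for v in same if abs(v) >= abs(es))
    p = min(1.0, 2.0 * (k + 1) / (len(same) + 1))
    return es, null, p


def logrank_oracle(time, event, group):
    """O/E/V tabulation at each event time; returns the chi-square."""
    levels = sorted(set(group))
    observed = expected = variance = 0.0
    for tj in sorted({t for t, e in zip(time, event) if e == 1}):
        n_j = sum(1 for t in time if t >= tj)
        n1_j = sum(1 for t, g in zip(time, group) if t >= tj and g == levels[0])
        d_j = sum(1 for t, e in zip(time, event) if t == tj and e == 1)
        d1_j = sum(
            1 for t, e, g in zip(time, event, group) if t == tj and e == 1 and g == levels[0]
        )
        observed += d1_j
        expected += d_j * n1_j / n_j
        if n_j > 1:
            variance += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    return (observed - expected) ** 2 / variance


def average_linkage_oracle(dist):
    """Naive O(n^3) average-linkage agglomeration.

    dist: full symmetric matrix as list of lists. Returns the merge sequence
    [(i, j, height, size), ...] with scipy-style cluster ids (new clusters
    numbered n, n+1, ...).
    """
    n = len(dist)
    active = {i: [i] for i in range(n)}  # cluster id -> leaf members
    d = {(i, j): dist[i][j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[a] + active[b]
        merges.append((min(a, b), max(a, b), h, len(members)))
        del active[a], active[b]
        # distance to the new cluster: unweighted average of leaf-pair distances
        for c in list(active):
            total = 0.0
            for u in active[c]:
                for v in members:
                    key = (min(u, v), max(u, v))
                    total += dist[key[0]][key[1]]
            d[(min(c, next_id), max(c, next_id))] = total / (len(active[c]) * len(members))
        active[next_id] = members
        d = {
            (i, j): v
            for (i, j), v in d.items()
            if i in active and j in active
        }
        next_id += 1
    return merges


def wilcoxon_exact_oracle(a, b):
    """Two-sided exact rank-sum p by enumerating all C(n1+n2, n1) assignments."""
    all_vals = list(a) + list(b)
    pooled_ranks = average_ranks(all_vals)
    n1 = len(a)
    n = len(all_vals)
    w_obs = sum(pooled_ranks[:n1])
    stats = [sum(pooled_ranks[i] for i in subset) for subset in combinations(range(n), n1)]
    mean_w = sum(stats) / len(stats)
    extreme = sum(1 for w in stats if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(stats)
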