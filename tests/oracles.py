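"""Brute-force reference implementations, written from the defining formulas.

These stay deliberately naive (explicit loops, no scipy/sklearn shortcuts for
the quantity under test) so they are independent of the library code paths
they check.
"""

import math


def rank_average(values):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y):
    return pearson(rank_average(x), rank_average(y))


def kendall_tau_b(x, y):
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(values):
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values())


def braycurtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def symmetric_kl(x, y, pseudocount=1e-6):
    p = [a + pseudocount for a in x]
    q = [b + pseudocount for b in y]
    sp, sq = sum(p), sum(q)
    p = [a / sp for a in p]
    q = [b / sq for b in q]
    kl_pq = sum(a * math.log(a / b) for a, b in zip(p, q))
    kl_qp = sum(b * math.log(b / a) for a, b in zip(p, q))
    return (kl_pq + kl_qp) / 2


def node_connectivity(adjacency, modules, node):
    """(within-module degree of `node`, participation coefficient)."""
    counts = {}
    for nb in adjacency[node]:
        m = modules[nb]
        counts[m] = counts.get(m, 0) + 1
    k = sum(counts.values())
    own = counts.get(modules[node], 0)
    part = 1 - sum((c / k) ** 2 for c in counts.values()) if k else 0.0
    return own, part


def within_module_z(adjacency, modules, node):
    own, _ = node_connectivity(adjacency, modules, node)
    members = [n for n in adjacency if modules[n] == modules[node]]
    owns = [node_connectivity(adjacency, modules, m)[0] for m in members]
    mean = sum(owns) / len(owns)
    var = sum((o - mean) ** 2 for o in owns) / len(owns)
    if var == 0:
        return 0.0
    return (own - mean) / math.sqrt(var)
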