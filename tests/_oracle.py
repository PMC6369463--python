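"""Independent brute-force oracle: plain scalar loops, no numpy vector ops.

Everything here recomputes the fuzzy-rough quantities from first
principles with explicit Python loops and ``math.log2``, deliberately
sharing no code path with the package, so oracle/implementation agreement
is meaningful.
"""

import math


def similarity(values, subset_idx, alpha):
    """n×n similarity as nested lists: per-attribute cut, min, final cut."""
    n = len(values)
    out = []
    for i in range(n):
        row = []
        for j in range(n):
            best = 1.0
            for a in subset_idx:
                d = abs(values[i][a] - values[j][a])
                s = 1.0 - d if d <= 1.0 - alpha else 0.0
                if s < best:
                    best = s
            if best < alpha:
                best = 0.0
            row.append(best)
        out.append(row)
    return out


def soft_count(S, T):
    """|S ∩ T|: nonzero S-entries not exceeding the matching T-entry."""
    c = 0
    for s, t in zip(S, T):
        if s > 0 and s <= t:
            c += 1
    return c


def rough_decision(sim, labels):
    """Class-mass shares per sample; class order by first appearance."""
    classes = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    n = len(sim)
    rd = []
    for i in range(n):
        total = sum(sim[i])
        rd.append(
            [
                sum(sim[i][j] for j in range(n) if labels[j] == c) / total
                for c in classes
            ]
        )
    return rd, classes


def cardinality(row):
    return sum(1 for v in row if v > 0)


def rough_entropy(sim):
    n = len(sim)
    return sum(math.log2(cardinality(row)) for row in sim) / n


def joint_entropy(sim_b, sim_c):
    n = len(sim_b)
    acc = 0.0
    for i in range(n):
        inter = [min(b, c) for b, c in zip(sim_b[i], sim_c[i])]
        acc += math.log2(cardinality(inter))
    return acc / n


def conditional_entropy(sim, labels):
    """E(RD | B) with the granule rows of ``sim`` and RD from ``sim_full``
    equal to ``sim`` itself when only one relation is in play; see
    :func:`conditional_entropy_vs` for distinct B and A."""
    return conditional_entropy_vs(sim, sim, labels)


def conditional_entropy_vs(sim_b, sim_full, labels):
    """E(RD | B) where granules come from sim_b and RD from sim_full."""
    rd, classes = rough_decision(sim_full, labels)
    n = len(sim_b)
    acc = 0.0
    for i in range(n):
        own = classes.index(labels[i])
        T = [rd[j][own] for j in range(n)]
        card = cardinality(sim_b[i])
        count = soft_count(sim_b[i], T)
        if count == 0:
            count = 1
        acc += math.log2(card / count)
    return acc / n
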