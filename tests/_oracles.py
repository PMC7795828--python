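"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain loops and none of the
package's own pipeline code, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import numpy as np


def jaccard_bitvector(a: set[int], b: set[int], universe: int) -> float:
    """Jaccard via explicit bit vectors over a finite universe."""
    va = np.zeros(universe, dtype=bool)
    vb = np.zeros(universe, dtype=bool)
    for i in a:
        va[i] = True
    for i in b:
        vb[i] = True
    union = int((va | vb).sum())
    if union == 0:
        return 1.0
    return int((va & vb).sum()) / union


def batch_patterns(slots: list[int], num_slots: int, theta: float, phi: float):
    """One-pass batch recomputation of candidate slots and retained runs.

    Returns (cs, runs) with runs as lists of slot indices.
    """
    counts = [0] * num_slots
    for s in slots:
        counts[s] += 1
    n = len(slots)
    sth = n * theta / num_slots
    cs = [c if c >= sth else 0 for c in counts]
    runs, current = [], []
    for i, v in enumerate(cs):
        if v > 0:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    kept = [r for r in runs if sum(cs[i] for i in r) >= phi * n]
    return cs, kept


def mamdani_dense(
    in_terms: dict,
    out_terms: dict,
    rules: list[tuple[str, str, str]],
    sens: float,
    sim: float,
    n_grid: int = 20001,
) -> float:
    """Dense-grid Mamdani + centroid, coded independently.

    ``in_terms`` maps term name -> point list for both inputs (shared
    shapes), ``out_terms`` likewise for the output; rules are
    (sens_term, sim_term, out_term) triples.
    """

    def mu(points, x):
        xs = [p[0] for p in points]
        ms = [p[1] for p in points]
        if x < xs[0] or x > xs[-1]:
            return 0.0
        for (x0, m0), (x1, m1) in zip(points, points[1:]):
            if x0 <= x <= x1:
                if x1 == x0:
                    return max(m0, m1)
                return m0 + (m1 - m0) * (x - x0) / (x1 - x0)
        return 0.0

    xs = np.linspace(0.0, 100.0, n_grid)
    agg = np.zeros(n_grid)
    for sens_term, sim_term, out_term in rules:
        act = min(mu(in_terms[sens_term], sens), mu(in_terms[sim_term], sim))
        if act <= 0:
            continue
        shape = np.array([mu(out_terms[out_term], x) for x in xs])
        agg = np.maximum(agg, np.minimum(act, shape))
    total = agg.sum()
    if total == 0:
        return float("nan")
    return float((xs * agg).sum() / total)
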