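"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: closures by exhaustive
path enumeration, frequency propagation by descendant scans, PR AUC by a
manual threshold sweep, weight search by exhaustive grid evaluation.
"""

import numpy as np


def closure_bruteforce(term, graph):
    """All nodes on any upward path from term to the root, by DFS enumeration."""
    paths = []

    def walk(node, path):
        path = path + [node]
        parents = graph.parents.get(node, ())
        if not parents:
            paths.append(path)
            return
        for p in sorted(parents):
            walk(p, path)

    walk(term, [])
    out = set()
    for path in paths:
        if path[-1] == graph.root:
            out.update(path)
    return frozenset(out)


def closure_of_set_bruteforce(terms, graph):
    out = set()
    for t in terms:
        out |= closure_bruteforce(t, graph)
    return frozenset(out)


def frequency_table_bruteforce(annotations, graph):
    """For each closure term t: max freq over annotated d with t in closure(d)."""
    keys = closure_of_set_bruteforce(annotations, graph)
    table = {}
    for t in keys:
        best = 0.0
        for d, f in annotations.items():
            if t in closure_bruteforce(d, graph):
                best = max(best, f)
        table[t] = best
    return table


def prob_given_disease_bruteforce(term, table, graph):
    """Exhaustive common-ancestor scan mirroring the stated probability rule."""
    if term in table.freq:
        return table.freq[term]
    common = [t for t in closure_bruteforce(term, graph) if t in table.freq]
    best = max(common, key=lambda t: (table.freq[t], t))
    n_term = max(1, len(graph.gene_sets.get(term, ())))
    n_ca = max(n_term, len(graph.gene_sets.get(best, ())))
    return table.freq[best] * n_term / n_ca


def pr_auc_sweep(scores, labels):
    """Step-wise PR area: sum of precision * recall increments over thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    auc = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = (labels & sel).sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return auc


def grid_search_weights(cases, step, bounds):
    """Exhaustive lattice search; lexicographically smallest argmax on ties."""
    lo, hi = bounds
    n = int(round((hi - lo) / step))
    best = None
    for i in range(n + 1):
        for j in range(n + 1):
            c1, c2 = lo + i * step, lo + j * step
            scores = np.concatenate(
                [c.log_lrs[:, 0] + c1 * c.log_lrs[:, 1] + c2 * c.log_lrs[:, 2]
                 for c in cases]
            )
            y = np.concatenate([c.labels for c in cases])
            auc = pr_auc_sweep(scores, y)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, (c1, c2))
    return best[1]
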