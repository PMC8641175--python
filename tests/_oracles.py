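"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the package implementation: the
bitmap oracle walks the CIGAR base by base, the clustering oracle takes
the transitive closure of the pairwise distance relation, and the AUC
oracle counts concordant pairs directly.
"""

import numpy as np

OP_CHARS = "MIDNSHP=X"
REF_CONSUMING = set("MDN=X")


def bitmap_walker(reference_start, cigar_ops, window_start, window_end, m):
    """Per-base reference-coordinate walk; 1 where a D op covers a base."""
    values = np.zeros(m, dtype=np.uint8)
    pos = reference_start
    for op, num in cigar_ops:
        ch = OP_CHARS[op] if isinstance(op, int) else op
        if ch in REF_CONSUMING:
            for _ in range(num):
                if ch == "D" and window_start <= pos < window_end:
                    values[pos - window_start] = 1
                pos += 1
    return values


def sort_then_slice(rows_with_names, n, m):
    """Feature-matrix oracle: stable sort by (count desc, name), slice, pad."""
    ordered = sorted(rows_with_names,
                     key=lambda rn: (-int(np.sum(rn[0])), rn[1]))
    out = np.zeros((n, m), dtype=np.uint8)
    for i, (row, _) in enumerate(ordered[:n]):
        out[i] = row
    return out


def transitive_closure_clusters(locations, radius):
    """Connected components of the |Li - Lj| < radius graph."""
    k = len(locations)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if abs(locations[i] - locations[j]) < radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()),
                  key=lambda g: min(locations[i] for i in g))


def pairwise_auc(scores, labels):
    """Concordant-pair count with 0.5 credit for score ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_cigar(rng, max_ops=8):
    """A random syntactically valid CIGAR starting and ending with M."""
    ops = [(0, int(rng.integers(1, 120)))]
    for _ in range(int(rng.integers(0, max_ops))):
        kind = rng.choice(["M", "I", "D", "N", "S", "=", "X"],
                          p=[.35, .1, .3, .05, .05, .075, .075])
        ops.append((OP_CHARS.index(kind), int(rng.integers(1, 250))))
    ops.append((0, int(rng.integers(1, 120))))
    return ops
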