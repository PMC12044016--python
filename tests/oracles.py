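"""Independent brute-force oracles used to pin the fast implementations.

Everything here is written as plainly as possible — explicit Python loops,
no shared code with the package — so a disagreement always implicates the
fast path.
"""

import itertools

import numpy as np


def local_mean_threshold_oracle(stack: np.ndarray, window: int, offset: float) -> np.ndarray:
    """Per-section sliding-window local-mean binarization, symmetric padding."""
    half = window // 2
    out = np.zeros(stack.shape, dtype=bool)
    for z in range(stack.shape[0]):
        padded = np.pad(stack[z].astype(float), half, mode="symmetric")
        for r in range(stack.shape[1]):
            for c in range(stack.shape[2]):
                win = padded[r:r + window, c:c + window]
                out[z, r, c] = stack[z, r, c] > win.mean() + offset
    return out


def phansalkar_threshold_oracle(stack: np.ndarray, window: int, offset: float,
                                k: float = 0.25, p: float = 2.0, q: float = 10.0,
                                r_param: float = 0.5) -> np.ndarray:
    """Per-section Phansalkar binarization on the max-normalized section."""
    half = window // 2
    out = np.zeros(stack.shape, dtype=bool)
    for z in range(stack.shape[0]):
        sec = stack[z].astype(float)
        scale = sec.max() if sec.max() else 1.0
        norm = sec / scale
        padded = np.pad(norm, half, mode="symmetric")
        for r in range(stack.shape[1]):
            for c in range(stack.shape[2]):
                win = padded[r:r + window, c:c + window]
                m = win.mean()
                s = win.std()
                t = m * (1 + p * np.exp(-q * m) + k * (s / r_param - 1))
                out[z, r, c] = sec[r, c] > t * scale + offset
    return out


def flood_fill_label_oracle(mask: np.ndarray) -> list[set]:
    """26-connected components as voxel-coordinate sets, by BFS flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros(mask.shape, dtype=bool)
    neighbours = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    components = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for d in neighbours:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(comp)
    return components


def greedy_pairing_oracle(pre_pts, post_pts, max_dist):
    """Greedy one-to-one matching by ascending distance, lexicographic ties.

    Points are (id, (x, y, z)) tuples; returns a set of (pre_id, post_id).
    """
    candidates = []
    for i, (pid, a) in enumerate(pre_pts):
        for j, (qid, b) in enumerate(post_pts):
            d = sum((a[k] - b[k]) ** 2 for k in range(3)) ** 0.5
            if d <= max_dist:
                candidates.append((d, pid, qid, i, j))
    candidates.sort()
    used_i, used_j, pairs = set(), set(), set()
    for d, pid, qid, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.add((pid, qid))
    return pairs


def optimal_pairing_oracle(pre_pts, post_pts, max_dist):
    """Maximum-cardinality, minimum-total-distance matching by enumeration.

    Exponential; intended for <= 8 objects per side.  Returns
    (cardinality, total_distance).
    """
    dists = {}
    for i, (_, a) in enumerate(pre_pts):
        for j, (_, b) in enumerate(post_pts):
            d = sum((a[k] - b[k]) ** 2 for k in range(3)) ** 0.5
            if d <= max_dist:
                dists[(i, j)] = d
    best = (0, 0.0)
    pre_ids = sorted({i for i, _ in dists})

    def extend(idx, used_j, card, total):
        nonlocal best
        if (card, -total) > (best[0], -best[1]):
            best = (card, total)
        if idx == len(pre_ids):
            return
        i = pre_ids[idx]
        extend(idx + 1, used_j, card, total)  # leave i unmatched
        for (ii, j), d in dists.items():
            if ii == i and j not in used_j:
                extend(idx + 1, used_j | {j}, card + 1, total + d)

    extend(0, frozenset(), 0, 0.0)
    return best


def spearman_oracle(x, y):
    """Pearson correlation of mid-ranks, computed with explicit loops."""
    def midranks(v):
        n = len(v)
        ranks = [0.0] * n
        for i in range(n):
            less = sum(1 for u in v if u < v[i])
            equal = sum(1 for u in v if u == v[i])
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def overlap_fraction_oracle(voxels_a: set, mask_b: np.ndarray) -> float:
    """Fraction of A's voxel set lying in B's foreground, counted one by one."""
    hits = sum(1 for v in voxels_a if mask_b[v])
    return hits / len(voxels_a)
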