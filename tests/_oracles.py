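"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive results by exhaustive search/enumeration and
stay independent of the implementation code paths they check.
"""

from collections import deque

import numpy as np


def bfs_all_event_distances(a, cn_cap):
    """Single-source BFS over +-1 contiguous-interval operations from
    profile ``a``: returns {state: minimal op count} for every reachable
    state with values in [0, cn_cap]. No operation may touch a bin currently
    at 0 (zero is absorbing)."""
    a = tuple(int(v) for v in a)
    n = len(a)
    dist = {a: 0}
    frontier = deque([a])
    while frontier:
        state = frontier.popleft()
        d = dist[state]
        for i in range(n):
            if state[i] == 0:
                continue
            for j in range(i + 1, n + 1):
                if state[j - 1] == 0:
                    break  # interval may not cross a zero bin
                window = state[i:j]
                for delta in (1, -1):
                    if delta == 1 and max(window) >= cn_cap:
                        continue
                    if delta == -1 and min(window) <= 0:
                        continue
                    new = (state[:i]
                           + tuple(v + delta for v in window)
                           + state[j:])
                    if new not in dist:
                        dist[new] = d + 1
                        frontier.append(new)
    return dist


def bfs_event_distance(a, b, cn_cap=8):
    """Minimum op count from a to b (inf when unreachable)."""
    dist = bfs_all_event_distances(a, cn_cap)
    return dist.get(tuple(int(v) for v in b), float("inf"))


def brute_force_best_arc(x):
    """Exhaustive max-|t| scan over all proper arcs (i, j]."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (0, n, -1.0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j - i == n:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            k, m = len(inside), len(outside)
            ss = (((inside - inside.mean()) ** 2).sum()
                  + ((outside - outside.mean()) ** 2).sum())
            sd = np.sqrt(ss / max(n - 2, 1))
            diff = abs(inside.mean() - outside.mean())
            if sd == 0:
                t = np.inf if diff > 1e-12 else 0.0
            else:
                t = diff / (sd * np.sqrt(1 / k + 1 / m))
            if t > best[2]:
                best = (i, j, t)
    return best


def brute_force_partition(X, gamma):
    """Exhaustive search over all breakpoint subsets of the penalized
    least-squares objective (cells x n, n small)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    cost = {}
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = X[:, i:j]
            cost[(i, j)] = float(
                ((seg - seg.mean(axis=1, keepdims=True)) ** 2).sum())
    best_obj, best_cuts = np.inf, None
    for mask in range(2 ** (n - 1)):
        cuts = [k + 1 for k in range(n - 1) if mask >> k & 1]
        edges = [0] + cuts + [n]
        obj = sum(cost[(p, q)] for p, q in zip(edges[:-1], edges[1:]))
        obj += gamma * len(cuts)
        if obj < best_obj - 1e-12:
            best_obj, best_cuts = obj, cuts
    return best_obj, best_cuts


def brute_force_ploidy_grid(means_linear, widths,
                            pmin=1.7, pmax=6.0, step=0.01,
                            tie_ploidy=2.0):
    """Plain loop over the printed ploidy grid minimizing the
    length-weighted rounding error (ties: closest to tie_ploidy, then
    smaller)."""
    r = np.asarray(means_linear, dtype=float)
    w = np.asarray(widths, dtype=float)
    r = r / np.average(r, weights=w)
    w = w / w.sum()
    best = None
    n_steps = int(round((pmax - pmin) / step))
    for k in range(n_steps + 1):
        p = pmin + step * k
        err = float(sum(wi * (ri * p - round(ri * p)) ** 2
                        for ri, wi in zip(r, w)))
        if best is None or err < best[1] - 1e-15:
            best = (p, err)
        elif abs(err - best[1]) <= 1e-15:
            closer = abs(p - tie_ploidy) < abs(best[0] - tie_ploidy) - 1e-12
            if closer:
                best = (p, err)
    return best
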