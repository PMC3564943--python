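"""Independent brute-force reimplementations used as test oracles.

Each function here recomputes a pipeline statistic by the most direct
method available (pairwise linkage, per-base loops, filter-and-recount)
and never calls into pas_scout, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math


def brute_single_linkage(positions, link_distance):
    """O(n^2) single-linkage clustering via union-find over all pairs."""
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= link_distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    clusters = []
    for members in groups.values():
        members.sort()
        counts = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        rep = max(counts, key=lambda p: (counts[p], p))
        clusters.append(
            {
                "position": rep,
                "support": len(members),
                "min": members[0],
                "max": members[-1],
            }
        )
    clusters.sort(key=lambda c: c["position"])
    return clusters


def brute_window_mean(values, start, end):
    """Mean over present values in [start, end); (mean, fraction present)."""
    present = [values[p] for p in range(start, end) if p in values]
    if not present:
        return math.nan, 0.0
    return sum(present) / len(present), len(present) / (end - start)


def brute_cdi(values, t_window, nt_window):
    t_mean, _ = brute_window_mean(values, *t_window)
    nt_mean, _ = brute_window_mean(values, *nt_window)
    return t_mean - nt_mean


def brute_cd(covered_positions, up, down):
    """CD from a set of covered base positions and two (start, end) pairs."""
    up_cov = sum(1 for p in range(*up) if p in covered_positions)
    down_cov = sum(1 for p in range(*down) if p in covered_positions)
    up_pct = 100.0 * up_cov / (up[1] - up[0])
    down_pct = 100.0 * down_cov / (down[1] - down[0])
    return up_pct, down_pct, up_pct - down_pct


def brute_fdr_curve(scores, supported):
    """Filter-then-count FDR at every distinct score.

    ``scores``: dict id -> score; ``supported``: dict id -> bool.
    Returns list of (cutoff, n, n_unsupported, fdr) sorted by
    descending cutoff.
    """
    out = []
    for cutoff in sorted(set(scores.values()), reverse=True):
        kept = [i for i, s in scores.items() if s >= cutoff]
        n_unsup = sum(1 for i in kept if not supported[i])
        out.append((cutoff, len(kept), n_unsup, n_unsup / len(kept)))
    return out


def brute_recovery(predictions, truths, tolerance):
    """O(n*m) matching: (sensitivity, empirical_fdr or None)."""
    matched_truth = sum(
        1 for t in truths if any(abs(t - p) <= tolerance for p in predictions)
    )
    matched_pred = sum(
        1 for p in predictions if any(abs(t - p) <= tolerance for t in truths)
    )
    sens = matched_truth / len(truths) if truths else math.nan
    efdr = (len(predictions) - matched_pred) / len(predictions) if predictions else None
    return sens, efdr
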