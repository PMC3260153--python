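"""Independent brute-force reference implementations used as oracles.

These deliberately use naive Python loops over the written definitions,
sharing no code with the package's optimized implementations.
"""

import numpy as np

GOOD, SOFT, BAD, MISS = 0, 1, 2, 3
AA, AB, BB, MISSING = 0, 1, 2, -1


def brute_maximal_windows(status, min_markers, max_soft, max_bad, max_miss,
                          edge_span=5, max_edge_deviations=1):
    """Enumerate every window, test the qualification rules directly,
    then discard windows contained in another qualifying window."""
    n = len(status)
    qualifying = []
    for left in range(n):
        for right in range(left, n):
            seg = [int(s) for s in status[left:right + 1]]
            if seg[0] != GOOD or seg[-1] != GOOD:
                continue
            if len(seg) < min_markers:
                continue
            if sum(s == SOFT for s in seg) > max_soft:
                continue
            if sum(s == BAD for s in seg) > max_bad:
                continue
            if sum(s == MISS for s in seg) > max_miss:
                continue
            z = min(edge_span, len(seg))
            lead, tail = seg[:z], seg[-z:]
            if any(s == BAD for s in lead) or any(s == BAD for s in tail):
                continue
            if sum(s in (SOFT, MISS) for s in lead) > max_edge_deviations:
                continue
            if sum(s in (SOFT, MISS) for s in tail) > max_edge_deviations:
                continue
            qualifying.append((left, right))
    maximal = [
        w for w in qualifying
        if not any(o != w and o[0] <= w[0] and o[1] >= w[1]
                   for o in qualifying)
    ]
    return sorted(maximal)


def brute_single_status(calls):
    out = []
    for c in calls:
        if c in (AA, BB):
            out.append(GOOD)
        elif c == AB:
            out.append(BAD)
        else:
            out.append(MISS)
    return np.array(out, dtype=np.int8)


def brute_shared_status(calls):
    """Per-marker status across samples: identical homozygosity with a
    single-deviant SOFT class."""
    n_samples, n_markers = calls.shape
    out = []
    for m in range(n_markers):
        col = [int(c) for c in calls[:, m] if c != MISSING]
        if not col:
            out.append(MISS)
            continue
        status = BAD
        for hom in (AA, BB):
            n_hom = sum(c == hom for c in col)
            if n_hom == len(col):
                status = GOOD
                break
            if n_hom == len(col) - 1 and n_hom >= 2:
                status = SOFT
        out.append(status)
    return np.array(out, dtype=np.int8)
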