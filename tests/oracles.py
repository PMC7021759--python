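"""Independent brute-force oracles used to validate the interval engine.

These deliberately avoid the package's data structures and algorithms:
plain tuples, quadratic scans, no sorting tricks.
"""

from __future__ import annotations


def tuples_overlap(a, b) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def brute_merge(tuples):
    """O(n^2) union of overlapping (seq, start, end) tuples."""
    regions = [list(t) for t in tuples]
    changed = True
    while changed:
        changed = False
        out = []
        while regions:
            cur = regions.pop()
            merged = False
            for other in out:
                if tuples_overlap(cur, other):
                    other[1] = min(other[1], cur[1])
                    other[2] = max(other[2], cur[2])
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(cur)
        regions = out
    return sorted(tuple(r) for r in regions)


def brute_overlap_flags(queries, subjects):
    """All-pairs overlap flags for (seq, start, end) tuples."""
    return [any(tuples_overlap(q, s) for s in subjects) for q in queries]


def brute_fragment_counts(fragments, peaks, max_size=2000):
    """Per-peak fragment counts by independent per-fragment scan."""
    counts = [0] * len(peaks)
    n_pass = 0
    for f in fragments:
        if f[2] - f[1] >= max_size:
            continue
        n_pass += 1
        for i, p in enumerate(peaks):
            if tuples_overlap(f, p):
                counts[i] += 1
    return counts, n_pass


def brute_reproducible(samples, support="any"):
    """Retained high peaks by quadratic scan.

    ``samples`` is a list of (high_tuples, low_tuples) pairs for one group.
    """
    retained = []
    for i, (highs, _) in enumerate(samples):
        others = [low for j, (_, low) in enumerate(samples) if j != i]
        for h in highs:
            hits = [any(tuples_overlap(h, l) for l in lows) for lows in others]
            if (any(hits) if support == "any" else all(hits)):
                retained.append(h)
    return brute_merge(retained)
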