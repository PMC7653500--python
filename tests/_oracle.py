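"""Independent brute-force oracle for the recursive MDLP discretizer.

Pure-Python, loop-based reimplementation of the same contract: best-gain
boundary-point cut, Fayyad-Irani acceptance inequality, pre-order
recursion, top-gain pruning.  Shares no code with the package so the two
routes check each other.
"""

from __future__ import annotations

import math


def oracle_entropy(pos: int, n: int) -> float:
    if n == 0 or pos == 0 or pos == n:
        return 0.0
    p = pos / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _blocks(pairs):
    """Distinct-value blocks [(value, n, pos), ...] of sorted pairs."""
    out = []
    for v, y in pairs:
        if out and out[-1][0] == v:
            out[-1][1] += 1
            out[-1][2] += y
        else:
            out.append([v, 1, y])
    return out


def oracle_cuts(values, labels, max_intervals):
    """Exhaustive recursive MDLP search; returns sorted accepted cuts."""
    pairs = sorted(zip([float(v) for v in values], [int(y) for y in labels]))
    blocks = _blocks(pairs)
    accepted = []  # (cut, gain) in acceptance order

    def segment(b0, b1):
        n = sum(b[1] for b in blocks[b0:b1])
        pos = sum(b[2] for b in blocks[b0:b1])
        return n, pos

    def recurse(b0, b1):
        n, pos = segment(b0, b1)
        if b1 - b0 < 2 or n < 2:
            return
        h_parent = oracle_entropy(pos, n)
        best = None  # (gain, edge)
        for e in range(b0 + 1, b1):
            ln, lp = segment(b0, e)
            rn, rp = segment(e, b1)
            left = blocks[e - 1]
            right = blocks[e]
            lpure = left[2] in (0, left[1])
            rpure = right[2] in (0, right[1])
            if lpure and rpure and (left[2] > 0) == (right[2] > 0):
                continue  # not a boundary point
            hl = oracle_entropy(lp, ln)
            hr = oracle_entropy(rp, rn)
            gain = h_parent - (ln * hl + rn * hr) / n
            if best is None or gain > best[0]:
                best = (gain, e, hl, hr, ln, lp, rn, rp)
        if best is None:
            return
        gain, e, hl, hr, ln, lp, rn, rp = best
        k = 1 if pos in (0, n) else 2
        k1 = 1 if lp in (0, ln) else 2
        k2 = 1 if rp in (0, rn) else 2
        delta = math.log2(3**k - 2) - (k * h_parent - k1 * hl - k2 * hr)
        if not gain > math.log2(n - 1) / n + delta / n:
            return
        cut = (blocks[e - 1][0] + blocks[e][0]) / 2.0
        accepted.append((cut, gain))
        recurse(b0, e)
        recurse(e, b1)

    recurse(0, len(blocks))
    keep = accepted
    if len(keep) > max_intervals - 1:
        order = sorted(range(len(keep)), key=lambda i: (-keep[i][1], i))
        keep = [keep[i] for i in sorted(order[: max_intervals - 1])]
    return sorted(c for c, _ in keep)
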