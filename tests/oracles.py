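"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the implementation: segments are
enumerated exhaustively over (start, start, length, direction), and
fragment runs are found by splitting the sorted pair list wherever the
consecutive-in-both-structures relation fails.
"""

from __future__ import annotations

import numpy as np


def exhaustive_best_segment_score(
    values: np.ndarray,
    qbreak: np.ndarray,
    mbreak: np.ndarray,
    mode: str,
) -> float:
    """Best segment score by enumerating every (alpha, beta, l, direction)."""
    n, m = values.shape
    best = 0.0
    directions = [1] if mode == "forward" else [1, -1]
    for step in directions:
        for alpha in range(n):
            for beta in range(m):
                total = 0.0
                length = 0
                while True:
                    qi = alpha + length
                    mi = beta + step * length
                    if not (0 <= qi < n and 0 <= mi < m):
                        break
                    if values[qi, mi] <= 0.0:
                        break
                    if length > 0:
                        if qbreak[qi]:
                            break
                        if step == 1 and mbreak[mi]:
                            break
                        if step == -1 and mbreak[mi + 1]:
                            break
                    total += values[qi, mi]
                    length += 1
                    best = max(best, total)
    return best


def brute_force_fragment_lengths(pairs) -> list[int]:
    """Fragment lengths: split the sorted pair list where runs break.

    A run continues from pair t to t+1 when the query index advances by one
    and the model index steps by a constant +/-1 fixed at the run's second
    member.
    """
    ordered = sorted((int(a), int(b)) for a, b in pairs)
    lengths: list[int] = []
    t = 0
    while t < len(ordered):
        end = t + 1
        step = None
        while end < len(ordered):
            dq = ordered[end][0] - ordered[end - 1][0]
            dm = ordered[end][1] - ordered[end - 1][1]
            if dq != 1 or abs(dm) != 1:
                break
            if step is None:
                step = dm
            elif dm != step:
                break
            end += 1
        lengths.append(end - t)
        t = end
    return sorted(lengths)
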