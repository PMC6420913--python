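"""Independent brute-force reference for the IR scanner.

Enumerates every (start, arm, spacer) triple and checks complementarity,
thresholds, outward maximality and containment directly against the
definitions; deliberately shares no code with the package's scanner.
"""

from __future__ import annotations

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pairs(a: str, b: str) -> bool:
    return _PAIR.get(a) == b


def brute_force_irs(
    seq: str,
    min_arm: int = 5,
    max_spacer: int = 8,
    min_total: int = 13,
) -> list[tuple[int, int, int, int]]:
    """All maximal, containment-pruned IRs as (start, end, arm, spacer)."""
    seq = seq.upper()
    L = len(seq)
    candidates: list[tuple[int, int, int, int]] = []
    for a in range(L):
        for s in range(max_spacer + 1):
            max_r = (L - a - s) // 2
            for r in range(min_arm, max_r + 1):
                if 2 * r + s < min_total:
                    continue
                b = a + 2 * r + s
                if not all(_pairs(seq[a + i], seq[b - 1 - i]) for i in range(r)):
                    continue
                # outward maximality: one more pair must be impossible
                if 0 < a and b < L and _pairs(seq[a - 1], seq[b]):
                    continue
                candidates.append((a, b, r, s))

    # identical intervals: keep the decomposition with the largest arm,
    # then the smallest spacer
    best: dict[tuple[int, int], tuple[int, int]] = {}
    for a, b, r, s in candidates:
        cur = best.get((a, b))
        if cur is None or (r, -s) > (cur[0], -cur[1]):
            best[(a, b)] = (r, s)
    deduped = [(a, b, r, s) for (a, b), (r, s) in best.items()]

    kept = [
        (a, b, r, s)
        for a, b, r, s in deduped
        if not any(
            c <= a and b <= d and (c, d) != (a, b) for c, d, _, _ in deduped
        )
    ]
    return sorted(kept)
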