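"""Independent brute-force oracles used to cross-check the estimators."""

from __future__ import annotations


def oracle_included_range(counts: list[int]) -> tuple[int, int]:
    """Included class range of the 50%-of-peak rule, by interval enumeration.

    Enumerates every contiguous class interval containing the tied-peak span
    and keeps the widest one in which each class either belongs to the peak
    span or has a count strictly above half the peak count.  Independent of
    the implementation's left/right growth procedure.
    """
    peak = max(counts)
    maxima = [i for i, c in enumerate(counts) if c == peak]
    lo0, hi0 = min(maxima), max(maxima)
    best = (lo0, hi0)
    for left in range(lo0 + 1):
        for right in range(hi0, len(counts)):
            ok = all(
                lo0 <= i <= hi0 or counts[i] > peak / 2.0
                for i in range(left, right + 1)
            )
            if ok and (right - left) > (best[1] - best[0]):
                best = (left, right)
    return best


def oracle_peak_class_mean(values: list[float], edges: list[float], counts: list[int]) -> float:
    """Mean of the raw values inside the oracle's included classes."""
    lo, hi = oracle_included_range(list(counts))
    picked = [v for v in values if edges[lo] <= v < edges[hi + 1]]
    return sum(picked) / len(picked)
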