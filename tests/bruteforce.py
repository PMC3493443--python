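"""Independent brute-force alignment oracles for the test suite.

These enumerate every monotone alignment path explicitly (no dynamic
programming), scoring affine gaps as open + extend for the first gap
residue and extend for each continuation — deliberately slow, simple and
independent of the package's aligner.
"""

from __future__ import annotations

from foxsurvey.pairwise import ScoringScheme


def best_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Maximum affine-gap global alignment score by exhaustive enumeration."""
    best = [float("-inf")]
    open_cost = scheme.gap_open + scheme.gap_extend
    extend_cost = scheme.gap_extend

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + scheme.pair_score(a[i], b[j]), "m")
        if i < len(a):  # gap in b
            cost = extend_cost if last == "a" else open_cost
            walk(i + 1, j, score - cost, "a")
        if j < len(b):  # gap in a
            cost = extend_cost if last == "b" else open_cost
            walk(i, j + 1, score - cost, "b")

    walk(0, 0, 0.0, "m")
    return best[0]


def best_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Maximum affine-gap local score: best global score over every pair of
    substrings, floored at zero (the empty alignment)."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    score = best_global_score(a[i1:i2], b[j1:j2], scheme)
                    if score > best:
                        best = score
    return best
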