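"""Independent brute-force oracles: literal loop transcriptions of the
coefficient definitions, kept free of KD-trees and vectorisation so they can
cross-check the optimised implementations."""

import math

import numpy as np

from emcoloc import DistanceBand, PointPattern, StudyWindow


def brute_pairs(pattern: PointPattern, band: DistanceBand) -> list[tuple[int, int]]:
    """Exhaustive O(n^2) double loop over the half-open pair definition."""
    pairs = []
    for j, a in enumerate(pattern.points_a):
        for q, b in enumerate(pattern.points_b):
            d = math.hypot(a[0] - b[0], a[1] - b[1])
            if band.r_lo <= d < band.r_hi:
                pairs.append((j, q))
    return pairs


def brute_cc2(patterns: list[PointPattern], band: DistanceBand) -> tuple[float, float]:
    """Literal transcription of the stage-2 average-of-ratios definition."""
    a_terms, b_terms = [], []
    for pat in patterns:
        pairs = brute_pairs(pat, band)
        if pat.n_a > 0:
            col_a = {j for j, _ in pairs}
            a_terms.append(len(col_a) / pat.n_a)
        if pat.n_b > 0:
            col_b = {q for _, q in pairs}
            b_terms.append(len(col_b) / pat.n_b)
    return (
        sum(a_terms) / len(a_terms) if a_terms else math.nan,
        sum(b_terms) / len(b_terms) if b_terms else math.nan,
    )


def brute_cc3(patterns: list[PointPattern], band: DistanceBand) -> tuple[float, float]:
    """Literal triple-loop transcription of the stage-3 densities (weights 1)."""
    k = len(patterns)
    total_ba = total_ab = 0.0
    for pat in patterns:
        pairs = brute_pairs(pat, band)
        n_col_a = len({j for j, _ in pairs})
        n_col_b = len({q for _, q in pairs})
        if n_col_a > 0 and pat.n_b > 0:
            for j in range(pat.n_a):
                inner = sum(1 for jj, _ in pairs if jj == j)
                total_ba += inner / (n_col_a * pat.n_b)
        if n_col_b > 0 and pat.n_a > 0:
            for q in range(pat.n_b):
                inner = sum(1 for _, qq in pairs if qq == q)
                total_ab += inner / (n_col_b * pat.n_a)
    return total_ba / k, total_ab / k


def random_pattern(
    rng: np.random.Generator,
    window: StudyWindow,
    n_max: int = 50,
    image_id: str = "img",
    n_min: int = 0,
) -> PointPattern:
    """A uniform random test pattern with label counts in [n_min, n_max]."""
    n_a = int(rng.integers(n_min, n_max + 1))
    n_b = int(rng.integers(n_min, n_max + 1))
    pts_a = rng.random((n_a, 2)) * [window.width, window.height]
    pts_b = rng.random((n_b, 2)) * [window.width, window.height]
    return PointPattern(image_id, window, pts_a, pts_b)
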