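"""Colocalization coefficients for dual-labelled point patterns.

The analysis quantifies, over a stack of k images, how particles of type A
(e.g. 6-nm gold, fibrillarin) co-distribute with particles of type B (e.g.
12-nm gold, PIP2).  A pair (A_j, B_q) is a *colocalizing pair* when its
Euclidean distance lies in the chosen half-open band [r_lo, r_hi).  Three
stages of coefficients are computed, each an unweighted average of per-image
ratios (never a pooled count):

* stage 1 — frequency: average absolute particle count per image
  (``cc1_abs``) and the average per-image proportions of each label
  (``cc1_rel_a``, ``cc1_rel_b``);
* stage 2 — relative aggregated colocalization: the average fraction of A
  (resp. B) particles that colocalize with at least one opposite particle
  (``cc2_a``, ``cc2_b``), combined with stage 1 into the four summary
  fractions of colocalizing / non-colocalizing particles of each label on the
  average image;
* stage 3 — relative colocalization density: the average fraction of
  opposite-type particles paired with an average *colocalizing* particle
  (``cc3_ba`` = density of B around a colocalizing A, ``cc3_ab`` the
  reverse), optionally boundary-corrected by the annulus edge weight.

Images where a ratio's denominator vanishes are excluded from that
coefficient's average (the effective image count is recorded per
coefficient); 0/0 is never silently treated as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import UndefinedCoefficientError
from .geometry import DistanceBand, EdgeWeightSpec, StudyWindow, edge_weights
from .patterns import PointPattern

__all__ = [
    "PairSet",
    "CoefficientSet",
    "IdentityReport",
    "find_colocalizing_pairs",
    "cc1_aggregate",
    "cc2",
    "summary_coefficients",
    "cc3",
    "compute_coefficients",
    "verify_identities",
    "ColocalizationCoefficients",
]


@dataclass(frozen=True)
class PairSet:
    """Colocalizing pairs of one image under one distance band.

    ``pairs`` holds (j, q) index pairs, j over A particles, q over B.
    ``counts_a[j]`` is the number of B particles paired with A_j (the inner
    sum of step-function indicators); an A particle colocalizes iff its count
    is positive, and ``n_col_a`` counts such particles (``n_col_b``
    analogously).
    """

    image_id: object
    band: DistanceBand
    pairs: tuple
    counts_a: np.ndarray
    counts_b: np.ndarray

    @property
    def n_col_a(self) -> int:
        return int((self.counts_a > 0).sum())

    @property
    def n_col_b(self) -> int:
        return int((self.counts_b > 0).sum())

    @property
    def indicator_a(self) -> np.ndarray:
        """Per-A colocalization indicator f(x_j) in {0, 1}."""
        return (self.counts_a > 0).astype(int)

    @property
    def indicator_b(self) -> np.ndarray:
        return (self.counts_b > 0).astype(int)


def find_colocalizing_pairs(pattern: PointPattern, band: DistanceBand) -> PairSet:
    """All (j, q) pairs with r_lo <= d(A_j, B_q) < r_hi.

    A KD-tree restricts candidates to d <= r_hi; the half-open membership is
    then decided by exact floating-point comparison on the recomputed
    distance, so the convention is strict at r_hi with no epsilon.
    """
    n_a, n_b = pattern.n_a, pattern.n_b
    counts_a = np.zeros(n_a, dtype=int)
    counts_b = np.zeros(n_b, dtype=int)
    pairs: list[tuple[int, int]] = []
    if n_a and n_b:
        tree = cKDTree(pattern.points_b)
        neighbours = tree.query_ball_point(pattern.points_a, band.r_hi)
        for j, candidates in enumerate(neighbours):
            for q in sorted(candidates):
                d = float(np.hypot(*(pattern.points_a[j] - pattern.points_b[q])))
                if band.r_lo <= d < band.r_hi:
                    pairs.append((j, q))
                    counts_a[j] += 1
                    counts_b[q] += 1
    return PairSet(pattern.image_id, band, tuple(pairs), counts_a, counts_b)


def _mean_over(values: list[float], name: str) -> tuple[float, int]:
    """Mean of the defined per-image terms; error if every image was excluded."""
    if not values:
        raise UndefinedCoefficientError(
            f"coefficient {name} is undefined: every image was excluded "
            "(zero denominator on all images)"
        )
    return float(np.mean(values)), len(values)


def cc1_aggregate(patterns: list[PointPattern]) -> tuple[float, float, float]:
    """Stage-1 frequency coefficients (cc1_abs, cc1_rel_a, cc1_rel_b).

    cc1_abs averages n_A + n_B over all k images; the relative coefficients
    average the per-image label proportions over images with at least one
    particle.  With no exclusions cc1_rel_a + cc1_rel_b == 1.
    """
    if not patterns:
        raise ValueError("cannot compute coefficients for an empty image stack")
    abs_terms = [p.n_a + p.n_b for p in patterns]
    rel_a = [p.n_a / (p.n_a + p.n_b) for p in patterns if p.n_a + p.n_b > 0]
    rel_b = [p.n_b / (p.n_a + p.n_b) for p in patterns if p.n_a + p.n_b > 0]
    return (
        float(np.mean(abs_terms)),
        _mean_over(rel_a, "cc1_rel_a")[0],
        _mean_over(rel_b, "cc1_rel_b")[0],
    )


def cc2(
    patterns: list[PointPattern], band: DistanceBand
) -> tuple[float, float]:
    """Stage-2 relative aggregated colocalization (cc2_a, cc2_b).

    cc2_a is the average over images (with n_A > 0) of the fraction of A
    particles colocalizing with at least one B; the two values are not
    complementary and each lies in [0, 1].
    """
    if not patterns:
        raise ValueError("cannot compute coefficients for an empty image stack")
    pair_sets = [find_colocalizing_pairs(p, band) for p in patterns]
    a_terms = [ps.n_col_a / p.n_a for p, ps in zip(patterns, pair_sets) if p.n_a > 0]
    b_terms = [ps.n_col_b / p.n_b for p, ps in zip(patterns, pair_sets) if p.n_b > 0]
    return _mean_over(a_terms, "cc2_a")[0], _mean_over(b_terms, "cc2_b")[0]


def summary_coefficients(
    cc1_rel_a: float, cc1_rel_b: float, cc2_a: float, cc2_b: float
) -> tuple[float, float, float, float]:
    """Summary fractions (coloc_a, noncoloc_a, coloc_b, noncoloc_b).

    coloc_a = cc1_rel_a * cc2_a and noncoloc_a = cc1_rel_a * (1 - cc2_a)
    (analogously for B): the proportion of all particles on the average image
    that are colocalizing / non-colocalizing particles of the given label.
    The four values sum to 1 whenever cc1_rel_a + cc1_rel_b = 1.
    """
    coloc_a = cc1_rel_a * cc2_a
    noncoloc_a = cc1_rel_a * (1.0 - cc2_a)
    coloc_b = cc1_rel_b * cc2_b
    noncoloc_b = cc1_rel_b * (1.0 - cc2_b)
    return coloc_a, noncoloc_a, coloc_b, noncoloc_b


def _cc3_one_side(
    pattern: PointPattern, pair_set: PairSet, spec: EdgeWeightSpec
) -> float:
    """Per-image stage-3 term for the density of B around colocalizing A.

    Sum over A particles of (1/w) * count_j / (n_colA * n_B); images with no
    colocalizing A (or no B) contribute 0 but still count in the outer 1/k.
    """
    n_col = pair_set.n_col_a
    if n_col == 0 or pattern.n_b == 0:
        return 0.0
    w = edge_weights(pattern.points_a, pair_set.band, pattern.window, spec)
    return float(np.sum(pair_set.counts_a / (w * n_col * pattern.n_b)))


def cc3(
    patterns: list[PointPattern],
    band: DistanceBand,
    spec: EdgeWeightSpec = EdgeWeightSpec(),
) -> tuple[float, float]:
    """Stage-3 relative colocalization densities (cc3_ba, cc3_ab).

    cc3_ba is the average (over all k images) fraction of B particles paired
    with an average colocalizing A particle; with weights off it lies in
    [0, 1], reaching 1 only when every colocalizing A pairs with every B.
    """
    if not patterns:
        raise ValueError("cannot compute coefficients for an empty image stack")
    ba_terms, ab_terms = [], []
    for pat in patterns:
        ps = find_colocalizing_pairs(pat, band)
        ba_terms.append(_cc3_one_side(pat, ps, spec))
        swapped = PairSet(ps.image_id, ps.band, ps.pairs, ps.counts_b, ps.counts_a)
        ab_terms.append(_cc3_one_side(pat.swapped(), swapped, spec))
    return float(np.mean(ba_terms)), float(np.mean(ab_terms))


@dataclass
class CoefficientSet:
    """All coefficients of one image stack under one band.

    ``per_image`` holds one row per image (counts and per-image coefficient
    values, NaN where undefined); ``aggregate`` the k-averaged coefficients;
    ``effective_counts`` how many images entered each average.
    """

    k: int
    band: DistanceBand
    edge_mode: str
    per_image: pd.DataFrame
    aggregate: dict
    effective_counts: dict
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_image = self.per_image.copy()
        records = []
        for rec in per_image.to_dict(orient="records"):
            records.append(
                {
                    key: (None if isinstance(val, float) and np.isnan(val) else val)
                    for key, val in rec.items()
                }
            )
        return {
            "parameters": {
                "band_nm": [self.band.r_lo, self.band.r_hi],
                "edge_correction": self.edge_mode,
                "k": self.k,
                **self.parameters,
            },
            "per_image": records,
            "aggregate": dict(self.aggregate),
            "effective_counts": dict(self.effective_counts),
        }


def compute_coefficients(
    patterns: list[PointPattern],
    band: DistanceBand,
    spec: EdgeWeightSpec = EdgeWeightSpec(),
) -> CoefficientSet:
    """Run the full three-stage pipeline on an image stack.

    Pair sets are found once per image and reused by every stage.  Aggregate
    summary fractions are the products of the aggregate stage-1 and stage-2
    coefficients, so the decomposition identities hold exactly whenever no
    image was excluded.
    """
    if not patterns:
        raise ValueError("cannot compute coefficients for an empty image stack")
    k = len(patterns)
    pair_sets = [find_colocalizing_pairs(p, band) for p in patterns]

    rows = []
    for pat, ps in zip(patterns, pair_sets):
        n, n_a, n_b = pat.n_a + pat.n_b, pat.n_a, pat.n_b
        rel_a = n_a / n if n else np.nan
        rel_b = n_b / n if n else np.nan
        c2a = ps.n_col_a / n_a if n_a else np.nan
        c2b = ps.n_col_b / n_b if n_b else np.nan
        swapped = PairSet(ps.image_id, ps.band, ps.pairs, ps.counts_b, ps.counts_a)
        rows.append(
            {
                "image_id": pat.image_id,
                "n_a": n_a,
                "n_b": n_b,
                "n_col_a": ps.n_col_a,
                "n_col_b": ps.n_col_b,
                "cc1_abs": float(n),
                "cc1_rel_a": rel_a,
                "cc1_rel_b": rel_b,
                "cc2_a": c2a,
                "cc2_b": c2b,
                "coloc_a": rel_a * c2a,
                "noncoloc_a": rel_a * (1.0 - c2a),
                "coloc_b": rel_b * c2b,
                "noncoloc_b": rel_b * (1.0 - c2b),
                "cc3_ba": _cc3_one_side(pat, ps, spec),
                "cc3_ab": _cc3_one_side(pat.swapped(), swapped, spec),
            }
        )
    per_image = pd.DataFrame(rows)

    effective: dict[str, int] = {"cc1_abs": k, "cc3_ba": k, "cc3_ab": k}
    aggregate: dict[str, float] = {"cc1_abs": float(per_image["cc1_abs"].mean())}
    rel_terms = per_image["cc1_rel_a"].dropna()
    aggregate["cc1_rel_a"], effective["cc1_rel_a"] = _mean_over(
        rel_terms.tolist(), "cc1_rel_a"
    )
    aggregate["cc1_rel_b"], effective["cc1_rel_b"] = _mean_over(
        per_image["cc1_rel_b"].dropna().tolist(), "cc1_rel_b"
    )
    aggregate["cc2_a"], effective["cc2_a"] = _mean_over(
        per_image["cc2_a"].dropna().tolist(), "cc2_a"
    )
    aggregate["cc2_b"], effective["cc2_b"] = _mean_over(
        per_image["cc2_b"].dropna().tolist(), "cc2_b"
    )
    (
        aggregate["coloc_a"],
        aggregate["noncoloc_a"],
        aggregate["coloc_b"],
        aggregate["noncoloc_b"],
    ) = summary_coefficients(
        aggregate["cc1_rel_a"],
        aggregate["cc1_rel_b"],
        aggregate["cc2_a"],
        aggregate["cc2_b"],
    )
    aggregate["cc3_ba"] = float(per_image["cc3_ba"].mean())
    aggregate["cc3_ab"] = float(per_image["cc3_ab"].mean())

    return CoefficientSet(
        k=k,
        band=band,
        edge_mode=spec.mode,
        per_image=per_image,
        aggregate=aggregate,
        effective_counts=effective,
    )


@dataclass(frozen=True)
class IdentityReport:
    """Residuals of the intrinsic algebraic identities of the coefficient set.

    ``exact`` is False when image exclusions make the identities only
    approximate (different effective k per coefficient); failures are
    reported, never raised.
    """

    residuals: dict
    tol: float
    exact: bool

    @property
    def passed(self) -> dict:
        return {name: abs(r) <= self.tol for name, r in self.residuals.items()}

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def verify_identities(cs: CoefficientSet, tol: float = 1e-12) -> IdentityReport:
    """Check the five intrinsic identities linking the coefficient stages.

    summary_sum_to_one: the four summary fractions sum to 1;
    partition_a / partition_b: coloc + noncoloc recovers the stage-1
    proportion of each label; ratio_a / ratio_b: coloc / stage-1 proportion
    recovers the stage-2 coefficient.
    """
    agg = cs.aggregate
    residuals = {
        "summary_sum_to_one": (
            agg["coloc_a"] + agg["noncoloc_a"] + agg["coloc_b"] + agg["noncoloc_b"]
        )
        - 1.0,
        "partition_a": (agg["coloc_a"] + agg["noncoloc_a"]) - agg["cc1_rel_a"],
        "partition_b": (agg["coloc_b"] + agg["noncoloc_b"]) - agg["cc1_rel_b"],
        "ratio_a": agg["coloc_a"] / agg["cc1_rel_a"] - agg["cc2_a"]
        if agg["cc1_rel_a"]
        else np.nan,
        "ratio_b": agg["coloc_b"] / agg["cc1_rel_b"] - agg["cc2_b"]
        if agg["cc1_rel_b"]
        else np.nan,
    }
    exact = len(set(cs.effective_counts.values())) == 1
    return IdentityReport(residuals=residuals, tol=tol, exact=exact)


class ColocalizationCoefficients(BaseEstimator):
    """Estimator computing the three-stage colocalization coefficients.

    Parameters
    ----------
    band : tuple (r_lo, r_hi)
        Half-open colocalization annulus in nm.  The band is the key
        scientific input; choose it from a significant distance range of the
        pair cross-correlation analysis.
    edge_correction : {"none", "annulus_fraction"}
        Boundary-effect weight applied in the stage-3 densities.  ``"none"``
        matches the unweighted worked-example arithmetic.
    quadrature_points : int
        Angular resolution of the numeric edge-weight fallback.

    Attributes (after :meth:`fit` on a list of :class:`PointPattern`)
    ----------
    result_ : CoefficientSet
    cc1_abs_, cc1_rel_a_, cc1_rel_b_, cc2_a_, cc2_b_, coloc_a_, noncoloc_a_,
    coloc_b_, noncoloc_b_, cc3_ba_, cc3_ab_ : float
    n_images_ : int
    """

    def __init__(
        self,
        band: tuple = (25.0, 125.0),
        edge_correction: str = "none",
        quadrature_points: int = 3600,
    ):
        self.band = band
        self.edge_correction = edge_correction
        self.quadrature_points = quadrature_points

    def _band(self) -> DistanceBand:
        if isinstance(self.band, DistanceBand):
            return self.band
        return DistanceBand(*map(float, self.band))

    def fit(self, X: list[PointPattern], y=None) -> "ColocalizationCoefficients":
        if not isinstance(X, (list, tuple)) or not all(
            isinstance(p, PointPattern) for p in X
        ):
            raise TypeError("X must be a list of PointPattern objects")
        spec = EdgeWeightSpec(self.edge_correction, self.quadrature_points)
        self.result_ = compute_coefficients(list(X), self._band(), spec)
        for name, value in self.result_.aggregate.items():
            setattr(self, f"{name}_", value)
        self.n_images_ = self.result_.k
        return self

    def identity_report(self, tol: float = 1e-12) -> IdentityReport:
        return verify_identities(self.result_, tol=tol)
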