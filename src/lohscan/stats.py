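"""Event-rate arithmetic, exact contingency tests, and karyotype clustering.

Rates are events per genome per cell division: a colony grown from a
single cell on a plate represents ~25 cell divisions, so a cohort of k
isolates with m called events gives m / (k * 25).  Rates are kept as
exact rationals and rounded only for reporting (one significant figure by
default, matching the field's convention of quoting e.g. 3 x 10^-2).

Fisher's exact test is implemented by full hypergeometric enumeration
with exact rational arithmetic; the two-tailed p-value sums the
probabilities of all tables (given the margins) no more probable than the
observed one -- the convention of the classic online calculators.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb, floor, log10

import numpy as np
from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage
from scipy.stats import beta

__all__ = [
    "RateEstimate",
    "event_rate",
    "round_sig",
    "fold_elevation",
    "fisher_exact_two_tailed",
    "sectored_frequency",
    "cluster_karyotypes",
    "KARYOTYPE_ENCODING",
]


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class RateEstimate:
    """Events per genome per division, exact and rounded."""

    n_events: int
    n_isolates: int
    divisions_per_isolate: int
    rate: Fraction

    @property
    def value(self) -> float:
        return float(self.rate)

    def rounded(self, sig: int = 1) -> float:
        return round_sig(float(self.rate), sig)


def event_rate(
    n_events: int, n_isolates: int, divisions_per_isolate: int = 25
) -> RateEstimate:
    """Exact event rate n_events / (n_isolates * divisions_per_isolate)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_isolates <= 0 or divisions_per_isolate <= 0:
        raise ValueError("isolate and division counts must be positive")
    rate = Fraction(n_events, n_isolates * divisions_per_isolate)
    return RateEstimate(n_events, n_isolates, divisions_per_isolate, rate)


def fold_elevation(
    rate: RateEstimate, baseline: RateEstimate, rounded: bool = False, sig: int = 1
) -> float:
    """Fold elevation of ``rate`` over ``baseline``.

    Unrounded mode divides the exact rational rates.  Rounded mode first
    rounds each rate to ``sig`` significant figures and divides those --
    the arithmetic used when quoting "about N times higher" from already
    rounded headline rates.
    """
    if baseline.rate == 0:
        raise ValueError("baseline rate must be positive")
    if rounded:
        b = baseline.rounded(sig)
        if b == 0:
            raise ValueError("baseline rounds to zero")
        return rate.rounded(sig) / b
    return float(rate.rate / baseline.rate)


@lru_cache(maxsize=200_000)
def _two_tailed_p(r1: int, r2: int, c1: int, a: int) -> Fraction:
    """Exact two-tailed Fisher p for table [[a, r1-a], [c1-a, r2-c1+a]].

    Enumerates the full hypergeometric support of tables with margins
    (r1, r2, c1) and sums P(x) for every x with P(x) <= P(a).
    """
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = comb(n, c1)
    pmf = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher's exact test on a 2x2 count table.

    ``table`` is [[a, b], [c, d]] of nonnegative integers.  The p-value is
    the exact sum of hypergeometric probabilities of all tables with the
    observed margins that are at most as probable as the observed table.
    Degenerate margins (an empty row or column) give p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table must have at least one positive margin")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    return float(_two_tailed_p(r1, r2, c1, a))


def sectored_frequency(
    n_sectored: int, n_colonies: int, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sectored-colony frequency with a Clopper-Pearson interval.

    Returns (point estimate, (lower, upper)).  The exact interval inverts
    the binomial tails; at x = 0 the lower bound is 0 (one-sided) and at
    x = n the upper bound is 1.
    """
    if n_colonies <= 0:
        raise ValueError("n_colonies must be positive")
    if not (0 <= n_sectored <= n_colonies):
        raise ValueError("n_sectored must be in 0..n_colonies")
    p = n_sectored / n_colonies
    alpha = 1.0 - conf
    lower = 0.0 if n_sectored == 0 else float(
        beta.ppf(alpha / 2, n_sectored, n_colonies - n_sectored + 1)
    )
    upper = 1.0 if n_sectored == n_colonies else float(
        beta.ppf(1 - alpha / 2, n_sectored + 1, n_colonies - n_sectored)
    )
    return p, (lower, upper)


#: Numeric encoding of whole-chromosome states for clustering: the copy
#: deviation from disomy.  UPD keeps two copies (0) and is additionally
#: carried as an indicator so UPD-rich isolates still cluster together.
KARYOTYPE_ENCODING = {
    "monosomy": -1,
    "normal": 0,
    "UPD": 0,
    "trisomy": 1,
    "tetrasomy": 2,
    "pentasomy": 3,
}


def encode_karyotypes(karyotypes: list) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric matrix (isolates x chromosomes) from Karyotype objects.

    Each chromosome contributes its copy deviation plus a parallel UPD
    indicator column; returns (matrix, isolate_ids, column_labels).
    """
    isolates = [k.isolate_id for k in karyotypes]
    chroms = list(karyotypes[0].states)
    m = np.zeros((len(karyotypes), 2 * len(chroms)))
    for i, k in enumerate(karyotypes):
        for j, chrom in enumerate(chroms):
            label = k.states[chrom][0]
            m[i, j] = KARYOTYPE_ENCODING[label]
            m[i, len(chroms) + j] = 1.0 if label == "UPD" else 0.0
    cols = chroms + [f"{c}_UPD" for c in chroms]
    return m, isolates, cols


def cluster_karyotypes(matrix: np.ndarray) -> dict:
    """Two-way agglomerative clustering of a numeric karyotype matrix.

    Complete linkage on Euclidean distances, both axes; deterministic
    given the input order.  Returns row/column leaf orderings, the two
    linkage matrices (merge heights in column 2), and text dendrograms.
    Single-row or single-column axes get identity orderings.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    out: dict = {}
    for axis, name in ((0, "row"), (1, "col")):
        data = matrix if axis == 0 else matrix.T
        if data.shape[0] < 2:
            out[f"{name}_order"] = list(range(data.shape[0]))
            out[f"{name}_linkage"] = None
            continue
        z = linkage(data, method="complete", metric="euclidean")
        out[f"{name}_order"] = [int(i) for i in leaves_list(z)]
        out[f"{name}_linkage"] = z
    return out


def dendrogram_text(z: np.ndarray, labels: list[str]) -> str:
    """Newick-like text rendering of a linkage matrix."""
    if z is None:
        return ";".join(labels)
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(z):
        nodes[n + k] = f"({nodes[int(i)]},{nodes[int(j)]}):{h:.4g}"
    return nodes[n + len(z) - 1] + ";"


def dendrogram_order(z: np.ndarray) -> list[int]:
    """Leaf order as scipy's dendrogram would draw it (no plotting)."""
    return [int(i) for i in dendrogram(z, no_plot=True)["leaves"]]
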