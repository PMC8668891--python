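"""Per-locus population-genetic statistics and the dataset-level ABC vector.

All statistics are functions of per-site derived-allele counts, computed on
biallelic 0/1 SNP matrices.  Counts of shared/fixed/exclusive site patterns
are reported per site (divided by locus length) so loci of different lengths
are comparable.  Statistics that are undefined at a locus (Tajima's D with
S = 0, F_ST at a pair-monomorphic locus, per-locus ABBA-BABA D with a zero
denominator) are returned as NaN and excluded from the dataset means/SDs.

The dataset summary is the ABC input: the mean and population standard
deviation (ddof = 0) across loci of every per-locus statistic, in a fixed
canonical ordering, plus the dataset-level ABBA-BABA D computed as the
ratio of summed numerators to summed denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from functools import lru_cache

import numpy as np

from .coalsim import SimulatedLocus

__all__ = [
    "LocusStats",
    "SummaryVector",
    "pi",
    "theta_w",
    "tajima_d",
    "divergence",
    "fst",
    "abba_baba_d",
    "site_pattern_counts",
    "locus_stats",
    "dataset_summary",
    "STAT_FIELDS",
    "SUMMARY_NAMES",
]


class StatisticUndefinedError(ValueError):
    """Raised when a statistic's preconditions are not met."""


# ---------------------------------------------------------------------------
# count-based kernels (single implementation behind the public functions)

def _derived_counts(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("SNP matrix must be 2-D (sequences x sites)")
    return m.sum(axis=0), m.shape[0]


def _pi_from_counts(c: np.ndarray, n: int, L: float) -> float:
    """Average pairwise difference per site from derived counts."""
    return float((c * (n - c)).sum() * 2.0 / (n * (n - 1)) / L)


@lru_cache(maxsize=None)
def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i**power).sum())


def _dxy_from_counts(cx: np.ndarray, nx: int, cy: np.ndarray, ny: int,
                     L: float) -> float:
    cross = cx * (ny - cy) + (nx - cx) * cy
    return float(cross.sum() / (nx * ny) / L)


def _tajima_d(k: float, S: int, n: int) -> float:
    if S <= 0 or n < 2:
        return float("nan")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((k - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# public per-statistic API

def pi(matrix: np.ndarray, L: float) -> float:
    """Nucleotide diversity: mean pairwise difference count per site."""
    c, n = _derived_counts(matrix)
    if n < 2:
        raise StatisticUndefinedError("pi requires at least 2 sequences")
    if L <= 0:
        raise ValueError("locus length must be positive")
    return _pi_from_counts(c, n, L)


def theta_w(S: int, n: int, L: float) -> float:
    """Watterson's estimator S / (a_n * L), a_n the (n-1)-th harmonic number."""
    if n < 2:
        raise StatisticUndefinedError("theta_w requires at least 2 sequences")
    if L <= 0:
        raise ValueError("locus length must be positive")
    return float(S / (_harmonic(n) * L))


def tajima_d(k: float, S: int, n: int) -> float:
    """Tajima's D from the mean pairwise difference count ``k`` and ``S``.

    Returns NaN when undefined (S = 0 or non-positive variance term).
    """
    if n < 2:
        raise StatisticUndefinedError("tajima_d requires at least 2 sequences")
    return _tajima_d(k, int(S), n)


def divergence(mat_x: np.ndarray, mat_y: np.ndarray, L: float) -> tuple[float, float]:
    """Gross (d_xy) and net (d_a) divergence between two populations.

    d_xy averages pairwise differences across all between-population pairs;
    d_a subtracts the mean within-population diversity and may be negative.
    When a population has a single sequence its pi is taken as 0.
    """
    cx, nx = _derived_counts(mat_x)
    cy, ny = _derived_counts(mat_y)
    if nx < 1 or ny < 1:
        raise StatisticUndefinedError("divergence requires non-empty populations")
    dxy = _dxy_from_counts(cx, nx, cy, ny, L)
    pix = _pi_from_counts(cx, nx, L) if nx >= 2 else 0.0
    piy = _pi_from_counts(cy, ny, L) if ny >= 2 else 0.0
    return dxy, dxy - (pix + piy) / 2.0


def fst(mat_x: np.ndarray, mat_y: np.ndarray, L: float,
        estimator: str = "within-total") -> float:
    """Pairwise F_ST; NaN when the pooled pair is monomorphic.

    The default is 1 - pi_within / pi_total with pi_within the unweighted
    mean of the two within-population diversities and pi_total the
    diversity of the pooled sample.  ``estimator="hudson"`` replaces the
    denominator with d_xy (1 - pi_within / d_xy).
    """
    cx, nx = _derived_counts(mat_x)
    cy, ny = _derived_counts(mat_y)
    if nx < 2 or ny < 2:
        raise StatisticUndefinedError("fst requires >= 2 sequences per population")
    pi_within = (_pi_from_counts(cx, nx, L) + _pi_from_counts(cy, ny, L)) / 2.0
    if estimator == "within-total":
        denom = _pi_from_counts(cx + cy, nx + ny, L)
    elif estimator == "hudson":
        denom = _dxy_from_counts(cx, nx, cy, ny, L)
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    if denom <= 0:
        return float("nan")
    return float(1.0 - pi_within / denom)


def abba_baba_d(p1: np.ndarray, p2: np.ndarray,
                p3: np.ndarray) -> tuple[float, float, float]:
    """Patterson's D from per-site derived-allele frequencies.

    Returns (D, numerator sum, denominator sum); D is NaN when the
    denominator is 0.  Sites must be polarized (0 = ancestral).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    abba = (1.0 - p1) * p2 * p3
    baba = p1 * (1.0 - p2) * p3
    num = float((abba - baba).sum())
    den = float((abba + baba).sum())
    d = num / den if den > 0 else float("nan")
    return d, num, den


def site_pattern_counts(mat_x: np.ndarray, mat_y: np.ndarray
                        ) -> tuple[int, int, int, int]:
    """Classify sites of a population pair.

    Returns (shared polymorphisms, fixed differences, polymorphisms
    exclusive to x, exclusive to y).  Sites monomorphic in the pooled pair
    are non-informative and counted in none of the categories.
    """
    cx, nx = _derived_counts(mat_x)
    cy, ny = _derived_counts(mat_y)
    if nx < 2 or ny < 2:
        raise StatisticUndefinedError("pattern counts require >= 2 sequences")
    poly_x = (cx > 0) & (cx < nx)
    poly_y = (cy > 0) & (cy < ny)
    fixed = ((cx == 0) & (cy == ny)) | ((cx == nx) & (cy == 0))
    shared = poly_x & poly_y
    excl_x = poly_x & ~poly_y
    excl_y = poly_y & ~poly_x
    return (int(shared.sum()), int(fixed.sum()),
            int(excl_x.sum()), int(excl_y.sum()))


# ---------------------------------------------------------------------------
# per-locus aggregation

_PAIR_IDX = {"12": (0, 1), "13": (0, 2), "23": (1, 2)}


@dataclass
class LocusStats:
    """All per-locus statistics in canonical field order."""

    pi_p1: float
    pi_p2: float
    pi_p3: float
    thetaw_p1: float
    thetaw_p2: float
    thetaw_p3: float
    tajd_p1: float
    tajd_p2: float
    tajd_p3: float
    dxy_12: float
    da_12: float
    fst_12: float
    ss_12: float
    sf_12: float
    sxa_12: float
    sxb_12: float
    dxy_13: float
    da_13: float
    fst_13: float
    ss_13: float
    sf_13: float
    sxa_13: float
    sxb_13: float
    dxy_23: float
    da_23: float
    fst_23: float
    ss_23: float
    sf_23: float
    sxa_23: float
    sxb_23: float
    d_num: float
    d_den: float


STAT_FIELDS = tuple(f.name for f in dc_fields(LocusStats))

SUMMARY_NAMES = tuple(
    f"{name}_{agg}" for name in STAT_FIELDS for agg in ("mean", "std")
) + ("abba_baba_D",)


@dataclass
class SummaryVector:
    """Fixed-order means-and-SDs vector used as ABC input."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SUMMARY_NAMES),):
            raise ValueError("summary vector has the wrong length")

    @property
    def names(self) -> tuple[str, ...]:
        return SUMMARY_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SUMMARY_NAMES, self.values.tolist()))


def locus_stats(locus: SimulatedLocus, fst_estimator: str = "within-total"
                ) -> LocusStats:
    """Compute the full per-locus statistic set from a 0/1 SNP matrix."""
    L = float(locus.length_bp)
    counts, ns = [], []
    for p in (0, 1, 2):
        mat = locus.pop_matrix(p)
        c, n = _derived_counts(mat)
        if n < 2:
            raise StatisticUndefinedError(
                "within-species statistics need >= 2 sequences per species"
            )
        counts.append(c)
        ns.append(n)

    within = {}
    for i, tag in enumerate(("p1", "p2", "p3")):
        c, n = counts[i], ns[i]
        S = int(((c > 0) & (c < n)).sum())
        pival = _pi_from_counts(c, n, L)
        within[f"pi_{tag}"] = pival
        within[f"thetaw_{tag}"] = S / (_harmonic(n) * L)
        within[f"tajd_{tag}"] = _tajima_d(pival * L, S, n)

    pairs = {}
    for tag, (i, j) in _PAIR_IDX.items():
        cx, nx, cy, ny = counts[i], ns[i], counts[j], ns[j]
        dxy = _dxy_from_counts(cx, nx, cy, ny, L)
        pix = _pi_from_counts(cx, nx, L)
        piy = _pi_from_counts(cy, ny, L)
        pairs[f"dxy_{tag}"] = dxy
        pairs[f"da_{tag}"] = dxy - (pix + piy) / 2.0
        if fst_estimator == "within-total":
            denom = _pi_from_counts(cx + cy, nx + ny, L)
        else:
            denom = dxy
        pairs[f"fst_{tag}"] = (1.0 - (pix + piy) / 2.0 / denom
                               if denom > 0 else float("nan"))
        poly_x = (cx > 0) & (cx < nx)
        poly_y = (cy > 0) & (cy < ny)
        fixed = ((cx == 0) & (cy == ny)) | ((cx == nx) & (cy == 0))
        pairs[f"ss_{tag}"] = float((poly_x & poly_y).sum() / L)
        pairs[f"sf_{tag}"] = float(fixed.sum() / L)
        pairs[f"sxa_{tag}"] = float((poly_x & ~poly_y).sum() / L)
        pairs[f"sxb_{tag}"] = float((poly_y & ~poly_x).sum() / L)

    freqs = [counts[i] / ns[i] for i in range(3)]
    _, num, den = abba_baba_d(*freqs)
    return LocusStats(**within, **pairs, d_num=num, d_den=den)


def dataset_summary(loci: list[LocusStats]) -> SummaryVector:
    """Mean and population SD across loci of every statistic.

    NaN entries (statistics undefined at a locus) are skipped per
    statistic; a statistic with no defined value across all loci
    contributes 0 to keep the vector finite.  The final entry is the
    dataset-level ABBA-BABA D (ratio of summed numerator to denominator).
    """
    if not loci:
        raise ValueError("dataset_summary requires at least one locus")
    table = np.array(
        [[getattr(ls, f) for f in STAT_FIELDS] for ls in loci], dtype=float
    )
    values = np.empty(len(SUMMARY_NAMES))
    valid = ~np.isnan(table)
    cnt = np.maximum(valid.sum(axis=0), 1)
    filled = np.where(valid, table, 0.0)
    means = filled.sum(axis=0) / cnt
    var = (valid * (filled - means) ** 2).sum(axis=0) / cnt
    stds = np.sqrt(var)
    all_nan = ~valid.any(axis=0)
    means[all_nan] = 0.0
    stds[all_nan] = 0.0
    values[0:-1:2] = means
    values[1:-1:2] = stds
    num_idx = STAT_FIELDS.index("d_num")
    den_idx = STAT_FIELDS.index("d_den")
    total_num = table[:, num_idx].sum()
    total_den = table[:, den_idx].sum()
    values[-1] = total_num / total_den if total_den > 0 else 0.0
    return SummaryVector(values=values)
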