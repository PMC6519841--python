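"""One- and two-dimensional site frequency spectra and derived statistics.

The joint (historic x modern) SFS is the central data object of the
inference framework: a ``(n1+1, n2+1)`` matrix ``X`` where ``X[i, j]`` counts
SNPs with derived-allele count ``i`` in the pooled historic sample and ``j``
in the pooled modern sample. Because allele frequencies are strongly
correlated across a ~90-generation interval, almost all mass concentrates
near the diagonal; demographic processes reshape how mass spreads away from
it, which is what the diagonal/anti-diagonal binning summarises for ABC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy.special import gammaln

from .snptable import SNPTable

__all__ = [
    "Spectrum2D",
    "BinnedSummary",
    "DiversityStats",
    "build_joint_sfs",
    "fold_joint_sfs",
    "project_joint_sfs",
    "bin_joint_sfs",
    "marginal_sfs",
    "diversity_stats",
    "bootstrap_spectra",
]

BinFamily = Literal["diagonal", "antidiagonal", "both"]


@dataclass
class Spectrum2D:
    """Joint site frequency spectrum over two pooled samples.

    ``counts[i, j]`` is the (possibly fractional, after projection) number of
    sites with derived count ``i`` of ``n1`` chromosomes in sample A
    (historic) and ``j`` of ``n2`` in sample B (modern).
    """

    counts: np.ndarray
    folded: bool = False
    polarized: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("spectrum must be a 2-D array")
        if np.any(self.counts < 0):
            raise ValueError("spectrum entries must be non-negative")

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def mass(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "Spectrum2D":
        return Spectrum2D(self.counts.copy(), self.folded, self.polarized)


@dataclass
class BinnedSummary:
    """Diagonal / anti-diagonal band sums of a square joint SFS.

    For an ``(n+1, n+1)`` spectrum with bin half-width ``w``, cells are
    partitioned into parallel bands of width ``2w + 1``:

    * diagonal family: by offset ``d = i - j``, band index
      ``b = round(d / (2w+1))`` (ties away from zero; with odd band width
      and integer offsets ties cannot occur);
    * anti-diagonal family: identically by ``s = i + j - n``.

    ``values[family][b]`` maps band index to its summed mass; each family is
    a partition of the cells, so each family's values sum to the spectrum
    mass. ``vector()`` returns the concatenation diagonal-then-antidiagonal,
    each family ordered by ascending band index — the ABC summary statistic.
    """

    width: int
    family: BinFamily
    values: dict = field(default_factory=dict)
    source_shape: tuple = ()

    def vector(self) -> np.ndarray:
        out: list[float] = []
        for fam in ("diagonal", "antidiagonal"):
            if fam in self.values:
                out.extend(v for _, v in sorted(self.values[fam].items()))
        return np.asarray(out, dtype=float)


@dataclass
class DiversityStats:
    """Classical SFS-based diversity summaries (per locus; per site if L given)."""

    S: int
    theta_w: float
    theta_pi: float
    tajima_d: float | None
    theta_w_per_site: float | None = None
    theta_pi_per_site: float | None = None


# ---------------------------------------------------------------------------
# construction


def build_joint_sfs(
    table: SNPTable,
    group_a,
    group_b,
    polarized: bool = True,
    polymorphic_only: bool = True,
) -> Spectrum2D:
    """Tally the joint SFS of two pooled group selections.

    Both selections must have a constant pooled chromosome total across
    sites (project afterwards with :func:`project_joint_sfs` to reconcile
    unequal totals coming from missing data). In polarized mode every site
    must have a known ancestral allele; in unpolarized mode counts are used
    as-is and the result should normally be folded downstream.
    """
    xa, na = table.pooled_counts(group_a)
    xb, nb = table.pooled_counts(group_b)
    if len(xa) == 0:
        raise ValueError("cannot infer sample sizes from an empty table; "
                         "use Spectrum2D(np.zeros((n1+1, n2+1))) directly")
    for name, n in (("A", na), ("B", nb)):
        if np.ptp(n) != 0:
            bad = table.site_id[n != n[0]]
            raise ValueError(
                f"group {name} chromosome totals vary across sites "
                f"(e.g. {list(bad[:5])}); project to a common size first"
            )
    if polarized and not np.all(table.is_polarized()):
        bad = table.site_id[~table.is_polarized()]
        raise ValueError(f"polarized spectrum requested but sites lack ancestral "
                         f"alleles (e.g. {list(bad[:5])})")
    n1, n2 = int(na[0]), int(nb[0])
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (xa, xb), 1.0)
    if polymorphic_only:
        counts[0, 0] = 0.0
        counts[n1, n2] = 0.0
    return Spectrum2D(counts, folded=False, polarized=polarized)


def fold_joint_sfs(s: Spectrum2D) -> Spectrum2D:
    """Fold an unfolded joint SFS onto minor-allele frequency classes.

    Cell ``(i, j)`` is reflected onto ``(n1-i, n2-j)``; mass lands on the
    cell with the smaller combined frequency ``i/n1 + j/n2``. On the
    self-symmetric boundary ``i/n1 + j/n2 == 1`` the cell and its image are
    summed once (a cell coinciding with its own image is left as is).
    """
    if s.folded:
        raise ValueError("spectrum is already folded")
    n1, n2 = s.n1, s.n2
    out = np.zeros_like(s.counts)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            # compare i/n1 + j/n2 with 1 in exact integer arithmetic
            lhs = i * n2 + j * n1
            if lhs < n1 * n2:
                out[i, j] = s.counts[i, j] + s.counts[n1 - i, n2 - j]
            elif lhs == n1 * n2:
                if (i, j) == (n1 - i, n2 - j):
                    out[i, j] = s.counts[i, j]
                elif i * n2 <= j * n1:  # keep one representative per pair
                    out[i, j] = s.counts[i, j] + s.counts[n1 - i, n2 - j]
    return Spectrum2D(out, folded=True, polarized=s.polarized)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """``(n+1, m+1)`` hypergeometric expectation matrix: row i gives the
    distribution of the derived count among m of n chromosomes."""
    if m > n:
        raise ValueError(f"cannot project up: m={m} > n={n}")
    i = np.arange(n + 1)[:, None]
    k = np.arange(m + 1)[None, :]

    def logc(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return out

    logw = logc(i, k) + logc(n - i, m - k) - logc(n, m)
    w = np.where((k <= i) & (m - k <= n - i), np.exp(logw), 0.0)
    return w


def project_joint_sfs(s: Spectrum2D, m1: int, m2: int) -> Spectrum2D:
    """Project each axis down to a smaller sample size in expectation.

    A count ``i`` of ``n`` maps to class ``k`` of ``m`` with hypergeometric
    weight ``C(i,k) C(n-i, m-k) / C(n,m)``; total mass is conserved and the
    result is generally fractional.
    """
    if m1 == s.n1 and m2 == s.n2:
        return s.copy()
    p1 = _projection_matrix(s.n1, m1)
    p2 = _projection_matrix(s.n2, m2)
    counts = p1.T @ s.counts @ p2
    return Spectrum2D(counts, folded=s.folded, polarized=s.polarized)


# ---------------------------------------------------------------------------
# binning


def band_index(offset: np.ndarray | int, w: int) -> np.ndarray | int:
    """Band index for integer offsets with band width ``2w + 1``; rounding is
    to the nearest band, ties away from zero (unreachable for odd widths)."""
    width = 2 * w + 1
    off = np.asarray(offset, dtype=float)
    b = np.sign(off) * np.floor(np.abs(off) / width + 0.5)
    b = b.astype(int)
    return b if b.ndim else int(b)


def bin_joint_sfs(s: Spectrum2D, w: int, family: BinFamily = "both") -> BinnedSummary:
    """Sum a square joint SFS into diagonal / anti-diagonal bands.

    Every band index reachable on the grid appears in the output (zero-mass
    bands included) so that bin vectors from equal-shaped spectra align.
    """
    if s.n1 != s.n2:
        raise ValueError(
            f"binning requires a square spectrum, got {s.counts.shape}; "
            "apply project_joint_sfs to the smaller axis first"
        )
    if w < 0:
        raise ValueError("bin width must be >= 0")
    n = s.n1
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    offsets = {"diagonal": i - j, "antidiagonal": i + j - n}
    fams = ("diagonal", "antidiagonal") if family == "both" else (family,)
    bmax = band_index(n, w)
    values: dict[str, dict[int, float]] = {}
    for fam in fams:
        b = band_index(offsets[fam], w)
        d: dict[int, float] = {k: 0.0 for k in range(-bmax, bmax + 1)}
        np_b = b.ravel()
        np_c = s.counts.ravel()
        for k in d:
            d[k] = float(np_c[np_b == k].sum())
        values[fam] = d
    return BinnedSummary(width=w, family=family, values=values, source_shape=s.counts.shape)


def marginal_sfs(s: Spectrum2D, axis: int | str = 0) -> np.ndarray:
    """Marginal 1-D SFS (axis 0 / "historic" rows, axis 1 / "modern" cols)."""
    if axis in (0, "historic", "a"):
        return s.counts.sum(axis=1)
    if axis in (1, "modern", "b"):
        return s.counts.sum(axis=0)
    raise ValueError(f"unknown axis {axis!r}")


# ---------------------------------------------------------------------------
# diversity statistics


def diversity_stats(eta: np.ndarray, n: int, L: float | None = None) -> DiversityStats:
    """Watterson's theta, pairwise diversity and Tajima's D from a 1-D SFS.

    ``eta`` holds the counts of the segregating classes ``eta_1..eta_{n-1}``
    (length n-1), or a full length n+1 spectrum whose monomorphic ends are
    ignored. Works on folded spectra too: a folded class i represents
    ``eta_i + eta_{n-i}`` and both theta_pi and theta_w are fold-invariant,
    so the folded vector may simply be padded with zeros above n/2.
    """
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    eta = np.asarray(eta, dtype=float)
    if len(eta) == n + 1:
        eta = eta[1:n]
    elif len(eta) != n - 1:
        raise ValueError(f"eta must have length n-1={n - 1} or n+1={n + 1}, got {len(eta)}")
    S = float(eta.sum())
    i = np.arange(1, n)
    a1 = np.sum(1.0 / np.arange(1, n))
    theta_w = S / a1
    theta_pi = float(np.sum(i * (n - i) * eta)) * 2.0 / (n * (n - 1))
    if S == 0:
        d = None
    else:
        a2 = np.sum(1.0 / np.arange(1, n) ** 2)
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        var = e1 * S + e2 * S * (S - 1)
        d = 0.0 if var == 0 else (theta_pi - theta_w) / math.sqrt(var)
    return DiversityStats(
        S=int(round(S)),
        theta_w=theta_w,
        theta_pi=theta_pi,
        tajima_d=d,
        theta_w_per_site=None if L is None else theta_w / L,
        theta_pi_per_site=None if L is None else theta_pi / L,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_spectra(
    table: SNPTable,
    group_a,
    group_b,
    B: int,
    seed: int,
    polarized: bool = False,
    polymorphic_only: bool = True,
) -> Iterator[Spectrum2D]:
    """Yield ``B`` site-bootstrap replicates of the joint SFS.

    Each replicate resamples sites with replacement to the original site
    count and retallies the spectrum; reproducible from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if table.n_sites == 0:
        raise ValueError("cannot bootstrap an empty table")
    rng = np.random.default_rng(seed)
    xa, na = table.pooled_counts(group_a)
    xb, nb = table.pooled_counts(group_b)
    if np.ptp(na) != 0 or np.ptp(nb) != 0:
        raise ValueError("bootstrap requires constant chromosome totals; project first")
    n1, n2 = int(na[0]), int(nb[0])
    for _ in range(B):
        idx = rng.integers(0, table.n_sites, size=table.n_sites)
        counts = np.zeros((n1 + 1, n2 + 1))
        np.add.at(counts, (xa[idx], xb[idx]), 1.0)
        if polymorphic_only:
            counts[0, 0] = 0.0
            counts[n1, n2] = 0.0
        yield Spectrum2D(counts, folded=False, polarized=polarized)
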