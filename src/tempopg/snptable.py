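"""Per-site biallelic allele-count tables for serially sampled populations.

A :class:`SNPTable` stores, for every SNP, the derived-allele count and the
total number of sampled chromosomes in each *group*, where a group is a
(period, deme) combination such as ``"hist:d0"`` or ``"mod:d2"``. Counts are
haploid chromosome counts throughout; diploid individuals contribute 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SNPTable",
    "group_label",
    "filter_snp_classes",
    "DEAMINATION_CLASSES",
    "UNPOLARIZED",
]

#: Sentinel allele value for sites whose ancestral/derived state is unknown.
UNPOLARIZED = "."

#: Post-mortem deamination damage classes: C->T and its reverse complement
#: G->A, stored as unordered base pairs so both orientations are caught.
DEAMINATION_CLASSES = (frozenset({"C", "T"}), frozenset({"G", "A"}))


def group_label(period: str, deme: str | int) -> str:
    """Canonical group label for a (period, deme) pair, e.g. ``"hist:d0"``."""
    d = f"d{deme}" if isinstance(deme, int) else str(deme)
    return f"{period}:{d}"


@dataclass
class SNPTable:
    """Ordered table of biallelic SNPs with per-group allele counts.

    Parameters
    ----------
    site_id, contig, position
        Per-site identifiers; positions are 1-based.
    anc, der
        Ancestral and derived allele per site (``UNPOLARIZED`` if unknown).
    x
        ``(n_sites, n_groups)`` integer array of derived-allele counts.
    n
        ``(n_sites, n_groups)`` integer array of sampled-chromosome totals.
    groups
        Group labels in column order of ``x`` / ``n``.
    """

    site_id: np.ndarray
    contig: np.ndarray
    position: np.ndarray
    anc: np.ndarray
    der: np.ndarray
    x: np.ndarray
    n: np.ndarray
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.site_id = np.asarray(self.site_id, dtype=object)
        self.contig = np.asarray(self.contig, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.anc = np.asarray(self.anc, dtype=object)
        self.der = np.asarray(self.der, dtype=object)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.groups = list(self.groups)
        if self.x.ndim != 2 or self.x.shape != self.n.shape:
            raise ValueError("x and n must be 2-D arrays of identical shape")
        if self.x.shape[1] != len(self.groups):
            raise ValueError(
                f"{self.x.shape[1]} count columns but {len(self.groups)} group labels"
            )
        if self.x.shape[0] != len(self.site_id):
            raise ValueError("count rows and site_id length differ")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            bad = self.site_id[np.any((self.x < 0) | (self.x > self.n), axis=1)]
            raise ValueError(f"derived counts outside [0, n] at sites {list(bad[:5])}")
        ids, counts = np.unique(self.site_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate site_ids: {list(ids[counts > 1][:5])}")

    # -- basic container protocol -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def __len__(self) -> int:
        return self.n_sites

    def take(self, idx: np.ndarray | Sequence[int]) -> "SNPTable":
        """New table with rows ``idx`` (order preserved, duplicates allowed
        only through resampling helpers that reassign site ids)."""
        idx = np.asarray(idx)
        return SNPTable(
            site_id=self.site_id[idx],
            contig=self.contig[idx],
            position=self.position[idx],
            anc=self.anc[idx],
            der=self.der[idx],
            x=self.x[idx],
            n=self.n[idx],
            groups=self.groups,
        )

    # -- group selection / pooling ------------------------------------------------

    def group_index(self, selector: str | Iterable[str]) -> np.ndarray:
        """Column indices for a selector.

        A selector is either an iterable of exact group labels or a single
        string: an exact label, or a period prefix such as ``"hist"`` that
        pools every ``"hist:*"`` group.
        """
        if isinstance(selector, str):
            if selector in self.groups:
                cols = [self.groups.index(selector)]
            else:
                cols = [i for i, g in enumerate(self.groups) if g.split(":")[0] == selector]
            if not cols:
                raise KeyError(f"selector {selector!r} matches no group in {self.groups}")
            return np.asarray(cols)
        cols = []
        for g in selector:
            if g not in self.groups:
                raise KeyError(f"unknown group {g!r}")
            cols.append(self.groups.index(g))
        return np.asarray(cols)

    def pooled_counts(self, selector) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (x, n) per site over the groups matched by ``selector``."""
        cols = self.group_index(selector)
        return self.x[:, cols].sum(axis=1), self.n[:, cols].sum(axis=1)

    def is_polarized(self) -> np.ndarray:
        """Boolean mask of sites with known ancestral/derived alleles."""
        return np.array(
            [a != UNPOLARIZED and d != UNPOLARIZED for a, d in zip(self.anc, self.der)],
            dtype=bool,
        )

    def drop_nonsegregating(self) -> "SNPTable":
        """Keep sites polymorphic in the union of all groups."""
        tot_x = self.x.sum(axis=1)
        tot_n = self.n.sum(axis=1)
        keep = (tot_x > 0) & (tot_x < tot_n)
        return self.take(np.nonzero(keep)[0])

    @staticmethod
    def empty(groups: Sequence[str]) -> "SNPTable":
        z = np.zeros((0, len(groups)), dtype=np.int64)
        e = np.empty(0, dtype=object)
        return SNPTable(e, e.copy(), np.zeros(0, dtype=np.int64), e.copy(), e.copy(), z, z.copy(), list(groups))


def filter_snp_classes(
    table: SNPTable,
    classes: Iterable[frozenset] = DEAMINATION_CLASSES,
) -> tuple[SNPTable, int]:
    """Remove SNPs whose allele pair falls in an excluded substitution class.

    By default removes every C/T and G/A site, the two classes produced by
    post-mortem cytosine deamination in degraded (museum / ancient) DNA.
    Classes are unordered base pairs, so both polarization orientations and
    the reverse-complement strand reading are covered.

    Returns the filtered table (site order preserved) and the number of
    sites removed.
    """
    classes = [frozenset(c) for c in classes]
    if not classes:
        return table, 0
    if not np.all(table.is_polarized()):
        raise ValueError("class filtering requires allele identities at every site")
    pairs = [frozenset((a, d)) for a, d in zip(table.anc, table.der)]
    keep = np.array([p not in classes for p in pairs], dtype=bool)
    removed = int((~keep).sum())
    return table.take(np.nonzero(keep)[0]), removed
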