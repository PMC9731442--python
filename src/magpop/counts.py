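"""Central pooled allele-count container (sync-compatible).

Pool-seq data give, for every reference position and every population pool,
the number of reads supporting each nucleotide.  The canonical on-disk form
is the PoPoolation2 "sync" table: contig, 1-based position, reference base,
and one ``A:T:C:G:N:del`` column per pool.  :class:`AlleleCountTable` is the
in-memory equivalent used by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: nucleotide order of a sync count column
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")
#: canonical tie-break order for alternative alleles
BASE_ORDER = ("A", "C", "G", "T")
_BASE_TO_SYNC = {b: SYNC_ORDER.index(b) for b in BASE_ORDER}


class ParameterError(ValueError):
    """Raised when an operation receives out-of-contract parameters."""


@dataclass
class AlleleCountTable:
    """Loci x pools nucleotide counts.

    Attributes
    ----------
    contigs, positions, ref
        Per-locus contig name, 1-based position, and reference base.
    counts
        Integer array of shape ``(n_loci, n_pools, 6)`` in ``A:T:C:G:N:del``
        order.
    pools
        Pool identifiers, in the column order of the source table.
    """

    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pools: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != len(SYNC_ORDER):
            raise ParameterError("counts must have shape (n_loci, n_pools, 6)")
        if np.any(self.counts < 0):
            raise ParameterError("negative allele counts")
        if not self.pools:
            self.pools = [f"pool_{i + 1}" for i in range(self.counts.shape[1])]
        if len(self.pools) != self.counts.shape[1]:
            raise ParameterError("pool registry does not match count columns")
        bad = ~np.isin(self.ref.astype(str), BASE_ORDER)
        if np.any(bad):
            raise ParameterError(
                f"reference base must be one of {BASE_ORDER}; offending loci: "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def coverage(self) -> np.ndarray:
        """Read depth per locus and pool, counting A/C/G/T only."""
        idx = [_BASE_TO_SYNC[b] for b in BASE_ORDER]
        return self.counts[:, :, idx].sum(axis=2)

    def ref_index(self) -> np.ndarray:
        """Sync-order column index of the reference base, per locus."""
        return np.array([_BASE_TO_SYNC[b] for b in self.ref.astype(str)], dtype=np.int64)

    def ref_counts(self) -> np.ndarray:
        """Reference-allele counts, shape (n_loci, n_pools)."""
        return np.take_along_axis(
            self.counts, self.ref_index()[:, None, None], axis=2
        )[:, :, 0]

    def alt_allele(self) -> np.ndarray:
        """Most frequent non-reference base over all pools combined.

        Ties are broken in the fixed order A < C < G < T.  Monomorphic loci
        (no non-reference reads at all) still get a deterministic alt from
        the same rule.
        """
        pooled = self.counts.sum(axis=1)  # loci x 6
        order_idx = [_BASE_TO_SYNC[b] for b in BASE_ORDER]
        acgt = pooled[:, order_idx].astype(float)  # loci x 4 in A,C,G,T order
        ref_col = np.array([BASE_ORDER.index(b) for b in self.ref.astype(str)], dtype=np.int64)
        acgt[np.arange(self.n_loci), ref_col] = -1.0
        # np.argmax takes the first maximum, which matches A<C<G<T
        alt_col = np.argmax(acgt, axis=1)
        return np.array([BASE_ORDER[i] for i in alt_col], dtype=object)

    def alt_counts(self, alt: np.ndarray | None = None) -> np.ndarray:
        """Counts of the (bi-allelic) alternative allele per locus and pool."""
        if alt is None:
            alt = self.alt_allele()
        alt_idx = np.array([_BASE_TO_SYNC[b] for b in alt.astype(str)], dtype=np.int64)
        return np.take_along_axis(self.counts, alt_idx[:, None, None], axis=2)[:, :, 0]

    def alt_frequencies(self) -> np.ndarray:
        """Bi-allelic alternative-allele frequency alt/(ref+alt) per pool.

        Positions where a pool has no ref or alt reads are returned as NaN.
        """
        ref_c = self.ref_counts().astype(float)
        alt_c = self.alt_counts().astype(float)
        denom = ref_c + alt_c
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(denom > 0, alt_c / np.where(denom > 0, denom, 1), np.nan)
        return freq

    def locus_ids(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.contigs.astype(str), self.positions], names=["contig", "position"]
        )

    def subset_pools(self, keep: list[str]) -> "AlleleCountTable":
        idx = [self.pools.index(p) for p in keep]
        return AlleleCountTable(
            self.contigs, self.positions, self.ref, self.counts[:, idx, :], list(keep)
        )

    def subset_loci(self, mask: np.ndarray) -> "AlleleCountTable":
        return AlleleCountTable(
            self.contigs[mask],
            self.positions[mask],
            self.ref[mask],
            self.counts[mask],
            list(self.pools),
        )
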