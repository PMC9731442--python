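"""Selection scans on pooled allele-frequency data.

Two complementary outlier tests:

* Lewontin–Krakauer (LK): for locus *l* across *n* populations,
  ``LK_l = (n - 1) * FST_l / mean(FST)``.  Under neutral drift in a single
  species the LK values follow a chi-squared distribution with ``n - 1``
  degrees of freedom, so departures of the empirical distribution flag
  either selection (upper-tail loci) or a species mixture (global misfit).

* PCA outlier scan on the B-allele-frequency (BAF) matrix, in the pool-seq
  style of pcadapt: loci are centred and scaled by the binomial standard
  deviation ``sqrt(p(1-p))`` of their mean frequency, the pool x locus
  matrix is decomposed by SVD, each locus is summarised by its loadings on
  the top K axes, and a robust Mahalanobis distance of those loading
  vectors (minimum covariance determinant) is converted to chi-squared
  p-values after dividing by the genomic inflation factor.

Both scans control the false discovery rate by Benjamini–Hochberg; loci
with q below the threshold (default 0.15) are candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .counts import AlleleCountTable, ParameterError
from .fst import informative_mask

logger = logging.getLogger(__name__)

__all__ = [
    "BafMatrix",
    "SelectionScanResult",
    "baf_from_counts",
    "lk_scan",
    "pca_outlier_scan",
    "detect_outlier_samples",
    "baf_report",
]


@dataclass
class BafMatrix:
    """Loci x pools B-allele (alternative-allele) frequencies in [0, 1]."""

    values: np.ndarray  # loci x pools
    loci: pd.MultiIndex  # (contig, position)
    pools: list
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
                raise ParameterError("BAF values must lie in [0, 1]")
        if np.any(np.all(np.isnan(self.values), axis=1)):
            raise ParameterError("all-missing locus in BAF matrix")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_pools(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.loci, columns=self.pools)

    def drop_pools(self, pools: list) -> "BafMatrix":
        keep = [i for i, p in enumerate(self.pools) if p not in set(pools)]
        return BafMatrix(
            self.values[:, keep],
            self.loci,
            [self.pools[i] for i in keep],
            self.maf_threshold,
        )


def baf_from_counts(
    counts: AlleleCountTable,
    min_count: int = 2,
    min_coverage: int = 4,
    max_coverage: int = 200,
) -> BafMatrix:
    """Bi-allelic alternative-allele frequencies for loci passing the
    calling window (same thresholds as variant calling)."""
    keep = informative_mask(counts, min_count, min_coverage, max_coverage)
    sub = counts.subset_loci(keep)
    freq = sub.alt_frequencies()
    freq = np.nan_to_num(freq, nan=0.0)
    return BafMatrix(values=freq, loci=sub.locus_ids(), pools=list(sub.pools))


@dataclass
class SelectionScanResult:
    """Per-locus scan statistics with FDR control."""

    table: pd.DataFrame  # index: loci; columns: statistic, p, q, candidate
    method: str
    n_populations: int
    q_threshold: float
    baf: pd.DataFrame | None = None  # per-pool BAF of the scanned loci
    genomic_inflation: float | None = None
    flagged_pools: list = field(default_factory=list)

    @property
    def candidates(self) -> pd.DataFrame:
        return self.table.loc[self.table["candidate"]]


def _bh_q(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def lk_scan(
    fst_per_locus: np.ndarray | pd.Series,
    n_populations: int,
    q_threshold: float = 0.15,
    loci: pd.MultiIndex | None = None,
    baf: pd.DataFrame | None = None,
) -> SelectionScanResult:
    """Lewontin–Krakauer outlier test against chi-squared(n-1).

    The per-locus FST vector should come from the joint multi-population
    estimator over the same pools; the scale cancels in the ratio, so LK is
    invariant to a constant rescaling of FST.
    """
    if n_populations < 2:
        raise ParameterError("LK test needs at least two populations")
    values = np.asarray(
        fst_per_locus.to_numpy() if isinstance(fst_per_locus, pd.Series) else fst_per_locus,
        dtype=float,
    )
    mean_fst = values.mean()
    if not mean_fst > 0:
        raise ParameterError("no differentiation to scan (mean FST = 0)")
    df = n_populations - 1
    lk = df * values / mean_fst
    p = stats.chi2.sf(lk, df)
    q = _bh_q(p)
    index = loci if loci is not None else pd.RangeIndex(values.size)
    table = pd.DataFrame(
        {"statistic": lk, "p": p, "q": q, "candidate": q < q_threshold}, index=index
    )
    return SelectionScanResult(
        table=table,
        method="lk",
        n_populations=n_populations,
        q_threshold=q_threshold,
        baf=baf,
    )


def _scaled_loadings(baf: BafMatrix, k: int, maf: float):
    """MAF filter, binomial scaling, SVD; returns (kept mask, z matrix).

    z has one row per kept locus: its loadings on the top-K left singular
    axes of the pool x locus matrix.
    """
    values = baf.values
    pbar = values.mean(axis=1)
    keep = np.minimum(pbar, 1.0 - pbar) >= maf
    if keep.sum() < max(k + 2, 10):
        raise ParameterError("too few loci pass the MAF filter")
    sub = values[keep]
    pbar = pbar[keep]
    scaled = (sub - pbar[:, None]) / np.sqrt(pbar * (1.0 - pbar))[:, None]
    mat = scaled.T  # pools x loci
    u, s, _ = np.linalg.svd(mat - mat.mean(axis=0), full_matrices=False)
    if not np.all(s[:k] > 1e-12):
        raise ParameterError("degenerate covariance; lower K")
    z = scaled @ u[:, :k]  # loci x K
    scores = u[:, :k] * s[:k]  # pools x K
    return keep, z, scores


def pca_outlier_scan(
    baf: BafMatrix,
    K: int | None = None,
    maf: float = 0.05,
    q_threshold: float = 0.15,
    seed: int = 0,
) -> SelectionScanResult:
    """PCA/Mahalanobis outlier scan on a BAF matrix (pool-seq mode).

    K defaults to ``n_pools - 1``.  Robust covariance of the per-locus
    loading vectors is estimated by minimum covariance determinant so that
    the outliers themselves do not inflate the null; distances are divided
    by the genomic inflation factor (median D-squared over the chi-squared
    median) before the chi-squared(K) tail probabilities.
    """
    n = baf.n_pools
    if n < 3:
        raise ParameterError("PCA scan needs at least three pools")
    k = (n - 1) if K is None else int(K)
    if not 1 <= k <= n - 1:
        raise ParameterError("K must lie in [1, n_pools - 1]")
    keep, z, _scores = _scaled_loadings(baf, k, maf)

    mcd = MinCovDet(random_state=seed).fit(z)
    d2 = mcd.mahalanobis(z)
    gif = float(np.median(d2) / stats.chi2.median(k))
    if gif <= 0:
        raise ParameterError("degenerate covariance; lower K")
    logger.info("PCA scan: K=%d, genomic inflation factor %.3f", k, gif)
    p = stats.chi2.sf(d2 / gif, k)
    q = _bh_q(p)
    loci = baf.loci[keep]
    table = pd.DataFrame(
        {"statistic": d2, "p": p, "q": q, "candidate": q < q_threshold}, index=loci
    )
    baf_frame = pd.DataFrame(baf.values[keep], index=loci, columns=baf.pools)
    return SelectionScanResult(
        table=table,
        method="pca",
        n_populations=n,
        q_threshold=q_threshold,
        baf=baf_frame,
        genomic_inflation=gif,
    )


def detect_outlier_samples(
    baf: BafMatrix, K: int | None = None, maf: float = 0.05, mad_factor: float = 6.0
) -> list:
    """Flag pools with aberrant placement in BAF PCA space.

    A pool is flagged when its score on any retained axis lies more than
    ``mad_factor`` median-absolute-deviations from the median score.  The
    caller may drop flagged pools and re-run the scan to avoid
    false-positive inflation.
    """
    n = baf.n_pools
    if n < 3:
        raise ParameterError("outlier-sample detection needs at least three pools")
    k = (n - 1) if K is None else int(K)
    _, _, scores = _scaled_loadings(baf, k, maf)
    flagged = set()
    for axis in range(scores.shape[1]):
        s = scores[:, axis]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad <= 0:
            continue
        for i in np.flatnonzero(np.abs(s - med) > mad_factor * mad):
            flagged.add(baf.pools[i])
    return sorted(flagged)


def baf_report(
    result: SelectionScanResult,
    loci: list | None = None,
    window: int = 10000,
) -> pd.DataFrame:
    """Long-format BAF table for candidate loci plus their neighbourhood.

    For each requested locus (default: the scan's candidates) the report
    contains one row per pool with the locus BAF, plus summary statistics of
    the surrounding window (default 10 kb, i.e. +/-5 kb) for Manhattan-style
    local views.  Windows are truncated at contig edges.
    """
    if result.baf is None:
        raise ParameterError("scan result carries no BAF matrix")
    targets = loci if loci is not None else list(result.candidates.index)
    if not targets:
        raise ParameterError("no candidate loci to report")
    half = window // 2
    all_loci = result.baf.index
    contigs = all_loci.get_level_values(0).to_numpy()
    positions = all_loci.get_level_values(1).to_numpy()
    rows = []
    for locus in targets:
        if locus not in result.baf.index:
            raise ParameterError(f"unknown locus {locus!r}")
        contig, pos = locus
        in_window = (
            (contigs == contig) & (positions >= pos - half) & (positions <= pos + half)
        )
        neighbour_stats = result.table.loc[all_loci[in_window], "statistic"]
        for pool in result.baf.columns:
            rows.append(
                {
                    "contig": contig,
                    "position": pos,
                    "pool": pool,
                    "baf": result.baf.loc[locus, pool],
                    "statistic": result.table.loc[locus, "statistic"],
                    "q": result.table.loc[locus, "q"],
                    "n_window_loci": int(in_window.sum()),
                    "window_mean_statistic": float(neighbour_stats.mean()),
                }
            )
    return pd.DataFrame(rows)
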