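"""Fixation-index estimation between population pools.

The default per-locus estimator is frequency based.  For two pools with
alternative-allele frequencies ``p1`` and ``p2``::

    p_bar = (p1 + p2) / 2
    H_T   = 2 p_bar (1 - p_bar)            # total expected heterozygosity
    H_S   = (2 p1 (1 - p1) + 2 p2 (1 - p2)) / 2
    FST   = (H_T - H_S) / H_T

FST ranges from 0 (no differentiation) to 1 (pools fixed for alternative
alleles).  Loci monomorphic across both pools (``H_T = 0``) carry no
information and are suppressed rather than scored 0.  A count-corrected
variant in the classical pool-seq style (finite coverage and finite pool
size) is available behind ``count_correction=True``; it is not the default
because the frequency-only form is the one the per-locus statistics and the
selection scans are built on.

Aggregation follows standard metapopulation practice: the median across
loci per pool pair is the differentiation proxy, pool pairs are aggregated
into regional means, and the per-locus distribution is checked for
unimodality (a multimodal FST distribution suggests a mixture of species
rather than one structured population).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import AlleleCountTable, ParameterError
from .dip import dip_test

logger = logging.getLogger(__name__)

__all__ = [
    "locus_fst",
    "multipop_locus_fst",
    "pairwise_fst",
    "fst_distribution_check",
    "region_fst",
    "differentiation_class",
    "FstResult",
]


def locus_fst(p1, p2, estimator: str = "nei"):
    """Per-locus FST from two pooled allele frequencies.

    Parameters
    ----------
    p1, p2
        Scalar or array alternative-allele frequencies in [0, 1].
    estimator
        ``"nei"`` (default): (H_T - H_S)/H_T as above.  ``"hudson"``:
        1 - H_w/H_b with H_b = p1(1-p2) + p2(1-p1), whose ratio of
        expectations is unbiased for the inbreeding parameter of an island
        model.

    Returns 0 where H_T (or H_b) is zero.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ParameterError("allele frequencies must lie in [0, 1]")
    if estimator == "nei":
        pbar = 0.5 * (p1 + p2)
        h_t = 2.0 * pbar * (1.0 - pbar)
        h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    elif estimator == "hudson":
        h_b = p1 * (1.0 - p2) + p2 * (1.0 - p1)
        h_w = p1 * (1.0 - p1) + p2 * (1.0 - p2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(h_b > 0, (h_b - h_w) / np.where(h_b > 0, h_b, 1.0), 0.0)
    else:
        raise ParameterError(f"unknown estimator {estimator!r}")
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def multipop_locus_fst(freqs: np.ndarray) -> np.ndarray:
    """Per-locus FST across n pools jointly.

    ``freqs`` has shape (n_pools, n_loci).  Generalises the two-pool
    estimator: H_T from the across-pool mean frequency, H_S as the mean of
    the per-pool expected heterozygosities.
    """
    freqs = np.asarray(freqs, dtype=float)
    pbar = freqs.mean(axis=0)
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = (2.0 * freqs * (1.0 - freqs)).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


@dataclass
class FstResult:
    """Per-locus pairwise FST plus median-aggregated matrices."""

    locus_values: pd.DataFrame  # columns: contig, position, pool_1, pool_2, fst
    median_matrix: pd.DataFrame  # pools x pools, NaN diagonal
    locus_counts: pd.DataFrame  # informative loci per pool pair
    pools: list[str] = field(default_factory=list)

    def pair_values(self, pool_1: str, pool_2: str) -> np.ndarray:
        lv = self.locus_values
        a, b = sorted((pool_1, pool_2))
        mask = (lv["pool_1"] == a) & (lv["pool_2"] == b)
        return lv.loc[mask, "fst"].to_numpy()


def _pool_correction(h: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """Small-sample correction h * n/(n-1), guarded for n <= 1."""
    n_eff = np.maximum(n_eff.astype(float), 2.0)
    return h * n_eff / (n_eff - 1.0)


def informative_mask(
    counts: AlleleCountTable,
    min_count: int = 2,
    min_coverage: int = 4,
    max_coverage: int = 200,
) -> np.ndarray:
    """Loci whose pooled minor-allele count and per-pool coverage pass the
    calling window (min-covered-fraction 1 semantics: every pool must lie in
    [min_coverage, max_coverage])."""
    if min_count < 1 or min_coverage < 1 or min_coverage > max_coverage:
        raise ParameterError("invalid coverage/count window")
    cov = counts.coverage()
    cov_ok = np.all((cov >= min_coverage) & (cov <= max_coverage), axis=1)
    ref_c = counts.ref_counts().sum(axis=1)
    alt_c = counts.alt_counts().sum(axis=1)
    minor = np.minimum(ref_c, alt_c)
    return cov_ok & (minor >= min_count)


def pairwise_fst(
    counts: AlleleCountTable,
    min_count: int = 2,
    min_coverage: int = 4,
    max_coverage: int = 200,
    estimator: str = "nei",
    count_correction: bool = False,
    pool_size: int = 500,
) -> FstResult:
    """Per-site pairwise FST for every pool pair, median aggregated.

    Frequencies are estimated per pool as alt/(ref+alt).  A locus enters a
    pool pair only if it passes the coverage/count window in *every* pool
    and is polymorphic for the pair (non-informative loci suppressed).
    Window and step size are one position: each site is scored on its own.
    """
    if counts.n_pools < 2:
        raise ParameterError("pairwise FST needs at least two pools")
    keep = informative_mask(counts, min_count, min_coverage, max_coverage)
    sub = counts.subset_loci(keep)
    freqs = sub.alt_frequencies()  # loci x pools
    cov = sub.coverage()
    pools = sub.pools
    n = len(pools)

    frames = []
    med = np.full((n, n), np.nan)
    cnt = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p1, p2 = freqs[:, i], freqs[:, j]
            valid = ~(np.isnan(p1) | np.isnan(p2))
            if estimator == "nei" and not count_correction:
                pbar = 0.5 * (p1 + p2)
                h_t = 2.0 * pbar * (1.0 - pbar)
                h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
            elif estimator == "nei" and count_correction:
                n1 = np.minimum(cov[:, i], 2 * pool_size)
                n2 = np.minimum(cov[:, j], 2 * pool_size)
                pbar = 0.5 * (p1 + p2)
                h_t = _pool_correction(
                    2.0 * pbar * (1.0 - pbar), np.minimum(n1 + n2, 4 * pool_size)
                )
                h_s = 0.5 * (
                    _pool_correction(2.0 * p1 * (1.0 - p1), n1)
                    + _pool_correction(2.0 * p2 * (1.0 - p2), n2)
                )
            elif estimator == "hudson":
                h_t = p1 * (1.0 - p2) + p2 * (1.0 - p1)
                h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
            else:
                raise ParameterError(f"unknown estimator {estimator!r}")
            informative = valid & (h_t > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                fst = (h_t - h_s) / np.where(h_t > 0, h_t, 1.0)
            fst = np.clip(fst[informative], 0.0, 1.0)
            cnt[i, j] = cnt[j, i] = fst.size
            if fst.size == 0:
                logger.warning("no informative loci for pools %s/%s", pools[i], pools[j])
                continue
            med[i, j] = med[j, i] = float(np.median(fst))
            a, b = sorted((pools[i], pools[j]))
            frames.append(
                pd.DataFrame(
                    {
                        "contig": sub.contigs[informative].astype(str),
                        "position": sub.positions[informative],
                        "pool_1": a,
                        "pool_2": b,
                        "fst": fst,
                    }
                )
            )
    locus_values = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "position", "pool_1", "pool_2", "fst"])
    )
    return FstResult(
        locus_values=locus_values,
        median_matrix=pd.DataFrame(med, index=pools, columns=pools),
        locus_counts=pd.DataFrame(cnt, index=pools, columns=pools),
        pools=list(pools),
    )


def fst_distribution_check(
    result: FstResult,
    pool_pair: tuple[str, str],
    n_bins: int = 50,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Histogram plus dip-test unimodality verdict for one pool pair.

    Returns ``(histogram, verdict)`` where histogram is ``(counts, edges)``
    and verdict is ``"unimodal"``, ``"multimodal"`` or ``"insufficient"``
    (fewer than 100 informative loci).  A multimodal population-wide FST
    distribution flags a possible species mixture in the recruited reads.
    """
    values = result.pair_values(*pool_pair)
    if values.size < 100:
        return (np.histogram(values, bins=n_bins, range=(0, 1)), "insufficient")
    stat, p = dip_test(values, n_boot=n_boot, seed=seed)
    verdict = "unimodal" if p >= alpha else "multimodal"
    return (np.histogram(values, bins=n_bins, range=(0, 1)), verdict)


def region_fst(
    median_matrices: pd.DataFrame | list[pd.DataFrame],
    regions: dict[str, str],
) -> pd.DataFrame:
    """Aggregate sample-level median FST into a region x region matrix.

    For each region pair the median pairwise FST values of all sample pairs
    spanning the two regions are collected — across genomes when several
    median matrices are supplied — and their mean is reported.  Regions
    without any admitted sample are dropped with a warning.
    """
    if isinstance(median_matrices, pd.DataFrame):
        median_matrices = [median_matrices]
    present = sorted({r for m in median_matrices for s in m.index if (r := regions.get(s))})
    dropped = sorted(set(regions.values()) - set(present))
    for r in dropped:
        warnings.warn(f"region {r!r} has no admitted samples; dropped", stacklevel=2)
    if len(present) < 2:
        raise ParameterError("need at least two regions with samples")
    out = pd.DataFrame(np.nan, index=present, columns=present)
    for a_i, ra in enumerate(present):
        for rb in present[a_i + 1 :]:
            vals = []
            for m in median_matrices:
                sa = [s for s in m.index if regions.get(s) == ra]
                sb = [s for s in m.index if regions.get(s) == rb]
                for x in sa:
                    for y in sb:
                        v = m.loc[x, y]
                        if not np.isnan(v):
                            vals.append(v)
            if vals:
                out.loc[ra, rb] = out.loc[rb, ra] = float(np.mean(vals))
    return out


def differentiation_class(fst_value: float) -> str:
    """Wright-style qualitative label for a differentiation value.

    ``< 0.05``: low; ``[0.05, 0.15)``: moderate-to-high; ``>= 0.15`` great.
    """
    if not 0.0 <= fst_value <= 1.0:
        raise ParameterError("FST must lie in [0, 1]")
    if fst_value < 0.05:
        return "low"
    if fst_value < 0.15:
        return "moderate-to-high"
    return "great"
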