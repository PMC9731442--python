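"""Sample-admission filter cascade for metagenome read recruitment.

Before any population-genetic statistic, every sample (one station/depth
mapped against one reference genome) must pass a cascade of checks designed
to reject non-specific recruitment:

1. read identity filter at 80%, then 97% (two-stage, by composition);
2. mean vertical coverage >= 4x (averaged over *all* reference positions,
   zeros included);
3. coverage breadth >= 80% (percent of positions with depth >= 1);
4. a unimodal depth distribution — operationalised as Hartigan's dip test
   with a bootstrap p-value on the nonzero-depth distribution (bimodal
   depth profiles betray recruitment from a mixture of genomes).

Relative abundance and cross-genome co-occurrence summaries operate on the
admitted samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .counts import ParameterError
from .dip import dip_test

logger = logging.getLogger(__name__)

__all__ = [
    "SampleRecruitment",
    "QCThresholds",
    "QCVerdict",
    "filter_reads_by_identity",
    "coverage_stats",
    "assess_unimodality",
    "admit_sample",
    "relative_abundance",
    "cooccurrence_matrix",
    "recruitment_from_alignment",
    "recruitment_from_tsv",
]


@dataclass
class SampleRecruitment:
    """Read-level summary of one sample mapped to one reference.

    ``reads`` optionally holds per-read intervals (columns ``identity``,
    ``start``, ``end``; 0-based half-open) enabling exact depth
    recomputation after identity filtering.  Without intervals the depth
    vector is thinned by the retained-read fraction (binomial-thinning
    expectation), which preserves the cascade semantics for fixtures that
    ship only an identity list and a depth vector.
    """

    sample_id: str
    identities: np.ndarray  # percent, one per mapped read
    depth: np.ndarray  # per reference position
    total_read_count: int
    mapped_read_count: int = 0
    reads: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.identities = np.asarray(self.identities, dtype=float)
        self.depth = np.asarray(self.depth)
        if self.identities.size and (
            self.identities.min() < 0 or self.identities.max() > 100
        ):
            raise ParameterError("read identities must lie in [0, 100]")
        if self.depth.size and self.depth.min() < 0:
            raise ParameterError("depths must be nonnegative")
        if not self.mapped_read_count:
            self.mapped_read_count = int(self.identities.size)
        if self.mapped_read_count > self.total_read_count:
            raise ParameterError("mapped reads exceed total reads")


@dataclass
class QCThresholds:
    min_identity_initial: float = 80.0
    min_identity_final: float = 97.0
    min_coverage: float = 4.0
    min_breadth: float = 80.0
    dip_alpha: float = 0.05
    dip_boot: int = 1000
    min_covered_positions: int = 100
    coverage_after_final_identity: bool = False
    seed: int = 0


@dataclass
class QCVerdict:
    sample_id: str
    mean_vertical_coverage: float
    coverage_breadth: float
    unimodality_statistic: float | None
    unimodality_p: float | None
    unimodality_pass: bool | None
    admitted: bool
    reasons: list = field(default_factory=list)


def filter_reads_by_identity(
    recruitment: SampleRecruitment, min_identity: float
) -> SampleRecruitment:
    """Retain reads with identity >= ``min_identity`` (percent).

    Two-stage filtering (80 then 97) is obtained by composing two calls.
    Depth is recomputed exactly when read intervals are available, otherwise
    scaled by the retained fraction.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ParameterError("min_identity must lie in [0, 100]")
    if recruitment.identities.size == 0:
        logger.warning("identity filter on empty recruitment %s", recruitment.sample_id)
        return replace(recruitment)
    keep = recruitment.identities >= min_identity
    identities = recruitment.identities[keep]
    if recruitment.reads is not None:
        reads = recruitment.reads.loc[
            recruitment.reads["identity"] >= min_identity
        ].reset_index(drop=True)
        depth = np.zeros(recruitment.depth.shape[0], dtype=np.int64)
        starts = reads["start"].to_numpy(dtype=np.int64)
        ends = np.minimum(reads["end"].to_numpy(dtype=np.int64), depth.size)
        np.add.at(depth, starts, 1)
        tail = ends[ends < depth.size]
        np.add.at(depth, tail, -1)
        depth = np.cumsum(depth)
    else:
        reads = None
        frac = keep.mean()
        depth = np.round(recruitment.depth.astype(float) * frac).astype(np.int64)
    return SampleRecruitment(
        sample_id=recruitment.sample_id,
        identities=identities,
        depth=depth,
        total_read_count=recruitment.total_read_count,
        mapped_read_count=int(identities.size),
        reads=reads,
    )


def coverage_stats(depth_vector: np.ndarray) -> tuple[float, float]:
    """(mean vertical coverage, coverage breadth in percent).

    The mean is taken over all reference positions, zeros included; breadth
    is the percentage of positions with depth >= 1.
    """
    depth = np.asarray(depth_vector)
    if depth.size == 0:
        raise ParameterError("empty depth vector")
    return float(depth.mean()), float(100.0 * np.count_nonzero(depth) / depth.size)


def assess_unimodality(
    depth_vector: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 1000,
    min_covered_positions: int = 100,
    seed: int = 0,
):
    """Dip-test verdict on the nonzero-depth distribution.

    Returns ``(statistic, p, status)`` with status ``"pass"``, ``"fail"``
    or ``"insufficient"`` (fewer than ``min_covered_positions`` covered
    positions — such samples are rejected outright).
    """
    depth = np.asarray(depth_vector)
    covered = depth[depth > 0].astype(float)
    if covered.size < min_covered_positions:
        return None, None, "insufficient"
    # depths are counts: dither ties so the stair-step ECDF of a unimodal
    # count distribution is not mistaken for multimodality
    rng = np.random.default_rng(seed + 2)
    covered = covered + rng.uniform(-0.5, 0.5, covered.size)
    stat, p = dip_test(covered, n_boot=n_boot, seed=seed)
    return stat, p, ("pass" if p >= alpha else "fail")


def admit_sample(
    recruitment: SampleRecruitment, thresholds: QCThresholds | None = None
) -> QCVerdict:
    """Run the full cascade and return an auditable verdict.

    By default coverage/breadth/unimodality are checked after the 80%
    identity stage (mirroring the mapping-then-inspection order), with the
    97% stage applied last; ``coverage_after_final_identity`` flips the
    coverage checks to the 97%-filtered reads.
    """
    thr = thresholds or QCThresholds()
    reasons: list = []
    stage1 = filter_reads_by_identity(recruitment, thr.min_identity_initial)
    stage2 = filter_reads_by_identity(stage1, thr.min_identity_final)
    basis = stage2 if thr.coverage_after_final_identity else stage1

    if basis.depth.size == 0:
        return QCVerdict(recruitment.sample_id, 0.0, 0.0, None, None, None, False, ["no depth data"])
    mean_cov, breadth = coverage_stats(basis.depth)
    if mean_cov < thr.min_coverage:
        reasons.append(f"mean_coverage<{thr.min_coverage:g}")
    if breadth < thr.min_breadth:
        reasons.append(f"breadth<{thr.min_breadth:g}")
    stat, p, status = assess_unimodality(
        basis.depth,
        alpha=thr.dip_alpha,
        n_boot=thr.dip_boot,
        min_covered_positions=thr.min_covered_positions,
        seed=thr.seed,
    )
    if status == "insufficient":
        reasons.append("insufficient covered positions")
    elif status == "fail":
        reasons.append("bimodal coverage distribution")
    if stage2.mapped_read_count == 0:
        reasons.append(f"no reads at identity>={thr.min_identity_final:g}")
    return QCVerdict(
        sample_id=recruitment.sample_id,
        mean_vertical_coverage=mean_cov,
        coverage_breadth=breadth,
        unimodality_statistic=stat,
        unimodality_p=p,
        unimodality_pass=(status == "pass") if status != "insufficient" else None,
        admitted=not reasons,
        reasons=reasons,
    )


def relative_abundance(mapped: int, total: int) -> float:
    """Percent of a sample's reads recruited by the reference genome."""
    if total <= 0:
        raise ParameterError("total read count must be positive")
    if mapped < 0 or mapped > total:
        raise ParameterError("mapped must lie in [0, total]")
    return 100.0 * mapped / total


def cooccurrence_matrix(abundance: pd.DataFrame):
    """Spearman rank correlation between genomes across samples.

    ``abundance`` is samples x genomes.  Returns ``(rho, p)`` DataFrames;
    a constant column yields NaN entries (correlation undefined).  Display
    convention: mask rho at p >= 0.05.
    """
    if abundance.shape[0] < 3:
        raise ParameterError("need at least 3 samples for co-occurrence")
    genomes = list(abundance.columns)
    n = len(genomes)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            x = abundance.iloc[:, i].to_numpy(dtype=float)
            y = abundance.iloc[:, j].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                logger.warning(
                    "constant abundance column (%s or %s); correlation undefined",
                    genomes[i],
                    genomes[j],
                )
                continue
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=genomes, columns=genomes),
        pd.DataFrame(pval, index=genomes, columns=genomes),
    )


def recruitment_from_alignment(
    path: str, sample_id: str, reference_length: int | None = None, total_read_count: int = 0
) -> SampleRecruitment:
    """Thin adapter extracting per-read identity and per-base depth from a
    SAM/BAM/CRAM alignment.

    Identity is 100 x (alignment columns - edit distance) / alignment
    columns, with gap columns counted in the denominator (requires the NM
    tag).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path) as bam:
        if reference_length is None:
            reference_length = sum(bam.lengths)
        offsets = {}
        run = 0
        for name, length in zip(bam.references, bam.lengths):
            offsets[name] = run
            run += length
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.cigartuples is None:
                continue
            columns = sum(
                ln for op, ln in read.cigartuples if op in (0, 1, 2, 7, 8)
            )  # M, I, D, =, X
            if columns == 0:
                continue
            nm = read.get_tag("NM") if read.has_tag("NM") else 0
            identity = 100.0 * (columns - nm) / columns
            start = offsets[read.reference_name] + read.reference_start
            rows.append((read.query_name, identity, start, start + read.reference_length))
    reads = pd.DataFrame(rows, columns=["read_id", "identity", "start", "end"])
    depth = np.zeros(reference_length, dtype=np.int64)
    if len(reads):
        np.add.at(depth, reads["start"].to_numpy(), 1)
        ends = reads["end"].to_numpy()
        np.add.at(depth, ends[ends < reference_length], -1)
        depth = np.cumsum(depth)
    return SampleRecruitment(
        sample_id=sample_id,
        identities=reads["identity"].to_numpy() if len(reads) else np.array([]),
        depth=depth,
        total_read_count=total_read_count or len(reads),
        reads=reads if len(reads) else None,
    )


def recruitment_from_tsv(
    identity_path: str, depth_path: str, sample_id: str, total_read_count: int
) -> SampleRecruitment:
    """Two-file TSV fixture: (read_id, identity) and (position, depth)."""
    ids = pd.read_csv(identity_path, sep="\t")
    dep = pd.read_csv(depth_path, sep="\t")
    depth = np.zeros(int(dep.iloc[:, 0].max()), dtype=np.int64)
    depth[dep.iloc[:, 0].to_numpy() - 1] = dep.iloc[:, 1].to_numpy()
    return SampleRecruitment(
        sample_id=sample_id,
        identities=ids.iloc[:, 1].to_numpy(dtype=float),
        depth=depth,
        total_read_count=total_read_count,
    )
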