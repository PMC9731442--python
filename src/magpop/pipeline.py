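"""Pipeline driver: QC -> variants -> FST -> selection scans -> environment.

The driver chains the analysis stages in the order the statistics require:
sample admission first (only admitted pools enter any genetic statistic),
then SNV calling and landscape summaries, per-site pairwise FST with median
aggregation, both selection scans on the B-allele-frequency matrix, and —
when at least three samples with nonzero genetic variance are admitted —
environmental variance partitioning with Mantel verification.  Every run
writes a provenance block (resolved configuration, seed, package version,
input digests) so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .counts import AlleleCountTable, ParameterError
from .env import euclidean_distance_matrix, preprocess_env, variance_partition
from .fst import multipop_locus_fst, pairwise_fst
from .io import (
    read_gff3,
    read_samples_tsv,
    read_sync,
    write_json_report,
    write_sync,
    write_vcf,
)
from .qc import QCThresholds, admit_sample
from .selection import baf_from_counts, detect_outlier_samples, lk_scan, pca_outlier_scan
from .variants import call_snvs, snv_density, tstv_ratio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths plus every stage threshold, at the analysis defaults.

    Thresholds: identity 80 then 97, mean coverage 4x, breadth 80%,
    min-count 2, coverage window [4, 200], pool size 500, MAF 0.05,
    q-threshold 0.15, 9,999 Mantel permutations.
    """

    counts_path: str | None = None
    annotation_path: str | None = None
    env_path: str | None = None
    output_dir: str = "magpop_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    min_count: int = 2
    min_coverage: int = 4
    max_coverage: int = 200
    pool_size: int = 500
    maf: float = 0.05
    q_threshold: float = 0.15
    mantel_permutations: int = 9999
    min_samples_env: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ParameterError("invalid coverage window")
        if self.min_count < 1:
            raise ParameterError("min_count must be >= 1")
        if not 0 <= self.maf < 0.5:
            raise ParameterError("maf must lie in [0, 0.5)")
        if not 0 < self.q_threshold < 1:
            raise ParameterError("q_threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    qc_verdicts: list
    admitted: list
    snvs: list
    landscape: dict
    fst: object
    lk: object | None
    pca: object | None
    flagged_pools: list
    env_partition: object | None
    env_skip_reason: str | None
    provenance: dict


def _digest(path: str | None) -> str | None:
    if path is None or not Path(path).exists():
        return None
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    counts: AlleleCountTable | None = None,
    samples: list | None = None,
    annotation=None,
    recruitments: list | None = None,
) -> PipelineResult:
    """Execute the full analysis.

    Inputs may be given as paths on the config or as in-memory objects
    (which take precedence).  Any stage error aborts with the stage name.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if counts is None:
        if config.counts_path is None:
            raise ParameterError("stage input: no counts given")
        counts = read_sync(config.counts_path)
    if annotation is None and config.annotation_path:
        annotation = read_gff3(config.annotation_path)
    if samples is None and config.env_path:
        samples = read_samples_tsv(config.env_path)

    # ---- stage 1: sample admission -------------------------------------
    verdicts = []
    if recruitments:
        for rec in recruitments:
            verdicts.append(admit_sample(rec, config.qc))
        admitted = [v.sample_id for v in verdicts if v.admitted]
        keep = [p for p in counts.pools if p in set(admitted)]
        if len(keep) < 2:
            raise ParameterError(f"stage qc: only {len(keep)} admitted pools")
        counts = counts.subset_pools(keep)
        if samples:
            samples = [s for s in samples if s.sample_id in set(keep)]
    else:
        admitted = list(counts.pools)
    logger.info("stage qc: %d admitted pools", len(admitted))

    # ---- stage 2: SNV landscape ----------------------------------------
    try:
        snvs = call_snvs(
            counts,
            min_count=config.min_count,
            min_coverage=config.min_coverage,
            max_coverage=config.max_coverage,
            annotation=annotation,
        )
    except Exception as exc:  # pragma: no cover - defensive context
        raise RuntimeError(f"stage variants failed: {exc}") from exc
    cov = counts.coverage()
    n_covered = int(
        np.sum(
            np.all((cov >= config.min_coverage) & (cov <= config.max_coverage), axis=1)
        )
    )
    landscape = {
        "n_snvs": len(snvs),
        "n_covered_positions": n_covered,
        "snv_density_percent": snv_density(snvs, n_covered) if n_covered else None,
        "tstv_ratio": tstv_ratio(snvs) if snvs else None,
        "context_counts": pd.Series(
            [s.context if s.context else "unavailable" for s in snvs]
        ).value_counts().to_dict(),
        "effect_counts": pd.Series(
            [s.effect if s.effect else "unavailable" for s in snvs]
        ).value_counts().to_dict(),
    }
    write_vcf(
        snvs,
        out / "variants.vcf",
        contig_lengths=(annotation.contig_lengths if annotation else None),
        pools=list(counts.pools),
    )

    # ---- stage 3: FST ---------------------------------------------------
    fst_res = pairwise_fst(
        counts,
        min_count=config.min_count,
        min_coverage=config.min_coverage,
        max_coverage=config.max_coverage,
    )
    fst_res.median_matrix.to_csv(out / "fst_median_matrix.tsv", sep="\t")
    fst_res.locus_values.to_csv(out / "fst_per_locus.tsv", sep="\t", index=False)

    # ---- stage 4: selection scans ---------------------------------------
    lk_res = pca_res = None
    flagged: list = []
    baf = baf_from_counts(
        counts, config.min_count, config.min_coverage, config.max_coverage
    )
    freqs = baf.values.T  # pools x loci
    locus_fst_vec = multipop_locus_fst(freqs)
    if locus_fst_vec.mean() > 0:
        lk_res = lk_scan(
            locus_fst_vec, counts.n_pools, q_threshold=config.q_threshold, loci=baf.loci
        )
        lk_res.table.to_csv(out / "scan_lk.tsv", sep="\t")
    if counts.n_pools >= 3:
        flagged = detect_outlier_samples(baf, maf=config.maf)
        scan_input = baf.drop_pools(flagged) if flagged and baf.n_pools - len(flagged) >= 3 else baf
        pca_res = pca_outlier_scan(
            scan_input, maf=config.maf, q_threshold=config.q_threshold, seed=config.seed
        )
        pca_res.flagged_pools = flagged
        pca_res.table.to_csv(out / "scan_pca.tsv", sep="\t")

    # ---- stage 5: environmental association -----------------------------
    env_part = None
    skip_reason = None
    gen_var = float(np.var(fst_res.median_matrix.to_numpy()[np.triu_indices(counts.n_pools, 1)]))
    if samples is None or len(samples) < config.min_samples_env:
        skip_reason = (
            f"fewer than {config.min_samples_env} admitted samples with metadata"
        )
    elif not gen_var > 0:
        skip_reason = "zero genetic variance between admitted samples"
    else:
        raw = pd.DataFrame(
            {v: [s.environment.get(v, np.nan) for s in samples] for v in
             samples[0].environment},
            index=[s.sample_id for s in samples],
        )
        env, report = preprocess_env(raw)
        dists = {
            var: euclidean_distance_matrix(env[var]) for var in env.columns
        }
        coords = np.array([[s.latitude, s.longitude] for s in samples], dtype=float)
        if not np.any(np.isnan(coords)):
            dists["geography"] = euclidean_distance_matrix(coords)
        order = [s.sample_id for s in samples]
        fst_m = fst_res.median_matrix.loc[order, order]
        env_part = variance_partition(
            fst_m,
            dists,
            mantel_permutations=config.mantel_permutations,
            seed=config.seed,
        )
        write_json_report(
            {
                "proportions": env_part.proportions,
                "fixed_unexplained": env_part.fixed_unexplained,
                "mantel": env_part.mantel,
                "vif": report["vif"],
            },
            out / "env_partition.json",
        )
    if skip_reason:
        logger.info("stage env skipped: %s", skip_reason)

    provenance = {
        "package": "magpop",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {
            "counts": _digest(config.counts_path),
            "annotation": _digest(config.annotation_path),
            "env": _digest(config.env_path),
        },
        "admitted_samples": admitted,
        "env_skip_reason": skip_reason,
    }
    with open(out / "provenance.json", "w") as handle:
        json.dump(provenance, handle, indent=2)

    return PipelineResult(
        qc_verdicts=verdicts,
        admitted=admitted,
        snvs=snvs,
        landscape=landscape,
        fst=fst_res,
        lk=lk_res,
        pca=pca_res,
        flagged_pools=flagged,
        env_partition=env_part,
        env_skip_reason=skip_reason,
        provenance=provenance,
    )
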