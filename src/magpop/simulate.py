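"""Synthetic metapopulation datasets with known truth.

Three generators cover the inputs of the analysis stages:

* :func:`simulate_metapopulation` — pooled allele counts for one species
  under an island model.  Each locus draws an ancestral frequency, every
  pool then draws its own frequency from the Balding–Nichols Beta
  construction (mean = ancestral frequency, shape scaled by
  ``(1-theta)/theta``), and read counts are binomial at a negative-binomial
  coverage.  A configurable subset of loci is "planted" with elevated
  differentiation to exercise the selection scans, and environmental
  variables can be linked to the realised genetic distances to exercise the
  variance partitioning.

  ``fst_target`` is expressed on the observable scale: it is the expected
  per-locus FST that the default frequency-based estimator reports for a
  pool pair at the configured coverage.  Because the per-locus ratio
  estimator is not an unbiased estimator of the Beta inbreeding parameter
  itself, the generator numerically inverts the mapping
  ``theta -> E[per-locus FST]`` (fixed internal Monte-Carlo, bisection) so
  that downstream estimates recover ``fst_target`` directly.

* :func:`simulate_annotation` — a toy multi-contig genome with stranded
  genes (UTRs, exons, introns, intergenic gaps) plus a mutation list whose
  realised transition:transversion ratio and effect-class proportions
  converge to requested values, for validating the landscape classifiers.

* :func:`simulate_coverage_profile` — per-base depth vectors and read
  identity histograms, unimodal or bimodal, for the recruitment-QC stage.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .counts import AlleleCountTable, ParameterError
from .samples import ARCTIC_REGIONS, ENV_VARIABLES, PopulationSample
from .variants import CODING, INTRON, UTR3, UTR5, Gene, GeneAnnotation, TRANSITIONS

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "Mutation",
    "CoverageProfile",
    "simulate_metapopulation",
    "simulate_annotation",
    "simulate_coverage_profile",
]

_BASES = ("A", "C", "G", "T")
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Conditions of a metapopulation simulation.

    Defaults mirror the study regime the pipeline is aimed at: a handful of
    population pools (3–9 per genome), thousands of bi-allelic loci,
    ~100x pooled coverage, weak background differentiation.
    """

    n_pools: int = 6
    n_loci: int = 5000
    fst_target: float = 0.05
    ancestral_maf_range: tuple = (0.1, 0.9)
    coverage_mean: float = 100.0
    coverage_dispersion: float = 0.05  # var = mu + dispersion * mu^2
    n_selected: int = 0
    fst_selected: float = 0.8
    env_link: dict = field(default_factory=dict)  # variable -> fraction
    tstv_ratio: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_pools < 2:
            raise ParameterError("n_pools must be at least 2")
        if not 0.0 <= self.fst_target < 1.0:
            raise ParameterError("fst_target must lie in [0, 1)")
        if self.n_selected:
            if not self.fst_target < self.fst_selected < 1.0:
                raise ParameterError("need fst_target < fst_selected < 1")
            if self.n_selected > self.n_loci:
                raise ParameterError("more selected loci than loci")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ParameterError("ancestral_maf_range must lie inside (0, 1)")
        if self.coverage_mean <= 0:
            raise ParameterError("coverage_mean must be positive")
        if self.coverage_dispersion < 0:
            raise ParameterError("coverage_dispersion must be nonnegative")
        for var, frac in self.env_link.items():
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"env_link[{var!r}] outside [0, 1]")
        if sum(self.env_link.values()) > 1.0 + 1e-9:
            raise ParameterError("env_link fractions must sum to at most 1")


@dataclass
class SimulatedDataset:
    counts: AlleleCountTable
    truth_selected: set  # {(contig, 1-based position)}
    truth_env_fractions: dict
    samples: list
    true_frequencies: np.ndarray  # pools x loci
    config: SimulationConfig
    annotation: GeneAnnotation | None = None


def _mean_locus_fst(theta: float, coverage: int, maf_range: tuple, rng: np.random.Generator,
                    n_loci: int = 60000) -> float:
    """Monte-Carlo mean of the per-locus frequency-based FST for one pool
    pair under Balding–Nichols(theta) at fixed binomial coverage."""
    p = rng.uniform(maf_range[0], maf_range[1], n_loci)
    if theta <= 0:
        f1 = f2 = p
    else:
        a = p * (1.0 - theta) / theta
        b = (1.0 - p) * (1.0 - theta) / theta
        f1 = rng.beta(a, b)
        f2 = rng.beta(a, b)
    c = max(int(round(coverage)), 1)
    p1 = rng.binomial(c, f1) / c
    p2 = rng.binomial(c, f2) / c
    pbar = 0.5 * (p1 + p2)
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    ok = h_t > 0
    if not np.any(ok):
        return 0.0
    return float(np.mean((h_t[ok] - h_s[ok]) / h_t[ok]))


@functools.lru_cache(maxsize=128)
def _theta_for_target(target: float, coverage: int, maf_lo: float, maf_hi: float) -> float:
    """Invert theta -> E[per-locus FST] by bisection (deterministic: the
    internal Monte-Carlo uses a fixed seed independent of the user seed)."""
    if target <= 0:
        return 0.0
    rng = np.random.default_rng(987654321)
    maf = (maf_lo, maf_hi)
    # the sampling floor: even theta=0 gives a small positive mean FST at
    # finite coverage; targets below it are unreachable and map to theta=0
    floor = _mean_locus_fst(0.0, coverage, maf, np.random.default_rng(987654321))
    if target <= floor:
        return 0.0
    lo, hi = 1e-6, 0.999
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        val = _mean_locus_fst(mid, coverage, maf, np.random.default_rng(987654321))
        if val < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-5:
            break
    return 0.5 * (lo + hi)


def _draw_pool_frequencies(rng, p, theta, n_pools):
    if theta <= 0:
        return np.tile(p, (n_pools, 1))
    a = p * (1.0 - theta) / theta
    b = (1.0 - p) * (1.0 - theta) / theta
    return rng.beta(a, b, size=(n_pools, p.size))


def _draw_coverage(rng, mean, dispersion, shape):
    if dispersion < 1e-8:
        return rng.poisson(mean, size=shape)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size=shape)


_ENV_UNITS = {
    # loc, scale used to map z-scores to plausible Arctic field values
    "temperature": (2.0, 2.0),
    "salinity": (34.0, 0.8),
    "oxygen": (320.0, 30.0),
    "ammonium": (0.05, 0.02),
    "iron": (0.4, 0.15),
    "nitrate": (6.0, 2.0),
    "nitrite": (0.15, 0.05),
    "phosphate": (0.7, 0.2),
    "silicate": (8.0, 3.0),
}


def _standardize(v):
    v = np.asarray(v, dtype=float)
    s = v.std()
    return (v - v.mean()) / (s if s > 0 else 1.0)


def _pair_d2(x, pair_index):
    return np.array([(x[i] - x[j]) ** 2 for i, j in pair_index])


def _linked_variable(rng, genetic_pairs, fraction, n_samples, pair_index):
    """Per-sample values whose squared pairwise distances correlate with the
    genetic distance structure at (approximately) the requested fraction.

    The genetic distance matrix is embedded in one dimension by classical
    multidimensional scaling; the variable mixes that embedding with
    independent noise, and the mixing weight is solved by bisection so the
    squared pairwise distances reach the requested R^2 against genetic
    distance.  The achievable linkage is capped by the quality of the 1-D
    embedding; the realised fraction is recorded as the truth.
    """
    g = _standardize(genetic_pairs)
    # classical MDS of the genetic structure, 1-D
    d2 = np.zeros((n_samples, n_samples))
    for (i, j), val in zip(pair_index, g - g.min()):
        d2[i, j] = d2[j, i] = val
    j_mat = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    k = -0.5 * j_mat @ d2 @ j_mat
    vals, vecs = np.linalg.eigh(k)
    if vals[-1] <= 0:
        return rng.normal(size=n_samples)
    g1 = _standardize(vecs[:, -1] * np.sqrt(vals[-1]))
    z = _standardize(rng.normal(size=n_samples))

    def realized(alpha):
        x = alpha * g1 + np.sqrt(max(1.0 - alpha**2, 0.0)) * z
        d = _pair_d2(x, pair_index)
        if d.std() == 0:
            return 0.0
        return float(np.corrcoef(d, genetic_pairs)[0, 1] ** 2)

    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) < fraction:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    return alpha * g1 + np.sqrt(max(1.0 - alpha**2, 0.0)) * z


def simulate_metapopulation(config: SimulationConfig) -> SimulatedDataset:
    """Generate a pooled-count dataset under the island model of one species.

    Deterministic given ``config`` (including its seed): identical configs
    produce bit-identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_loci, n_pools = config.n_loci, config.n_pools
    lo, hi = config.ancestral_maf_range

    p = rng.uniform(lo, hi, n_loci)
    theta = _theta_for_target(
        round(config.fst_target, 6), int(round(config.coverage_mean)), lo, hi
    )
    freqs = _draw_pool_frequencies(rng, p, theta, n_pools)

    selected_idx = np.array([], dtype=int)
    if config.n_selected:
        theta_sel = _theta_for_target(
            round(config.fst_selected, 6), int(round(config.coverage_mean)), lo, hi
        )
        selected_idx = np.sort(
            rng.choice(n_loci, size=config.n_selected, replace=False)
        )
        freqs[:, selected_idx] = _draw_pool_frequencies(
            rng, p[selected_idx], theta_sel, n_pools
        )

    cov = _draw_coverage(
        rng, config.coverage_mean, config.coverage_dispersion, (n_pools, n_loci)
    )
    alt_c = rng.binomial(cov, freqs)
    ref_c = cov - alt_c

    ref_base = rng.choice(_BASES, size=n_loci)
    is_ts = rng.random(n_loci) < config.tstv_ratio / (config.tstv_ratio + 1.0)
    alt_base = np.empty(n_loci, dtype=object)
    for i in range(n_loci):
        r = ref_base[i]
        if is_ts[i]:
            alt_base[i] = _TRANSITION_OF[r]
        else:
            tv = [b for b in _BASES if b != r and b != _TRANSITION_OF[r]]
            alt_base[i] = tv[int(rng.integers(2))]

    sync_idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    counts = np.zeros((n_loci, n_pools, 6), dtype=np.int64)
    for i in range(n_loci):
        counts[i, :, sync_idx[ref_base[i]]] += ref_c[:, i]
        counts[i, :, sync_idx[alt_base[i]]] += alt_c[:, i]

    positions = np.arange(1, n_loci + 1) * 10
    contigs = np.full(n_loci, "sim_contig_1", dtype=object)
    table = AlleleCountTable(
        contigs,
        positions,
        ref_base.astype(object),
        counts,
        [f"pool_{i + 1:02d}" for i in range(n_pools)],
    )

    pair_index = [(i, j) for i in range(n_pools) for j in range(i + 1, n_pools)]
    gpairs = np.array(
        [np.mean((freqs[i] - freqs[j]) ** 2) for i, j in pair_index]
    )

    env_z = {}
    truth_env = {}
    for var in ENV_VARIABLES:
        frac = config.env_link.get(var, 0.0)
        if frac > 0 and gpairs.std() > 0:
            x = _linked_variable(rng, gpairs, frac, n_pools, pair_index)
            x = _standardize(x)
            d2 = np.array([(x[i] - x[j]) ** 2 for i, j in pair_index])
            if d2.std() > 0:
                truth_env[var] = float(np.corrcoef(d2, gpairs)[0, 1] ** 2)
            else:
                truth_env[var] = 0.0
        else:
            x = rng.normal(size=n_pools)
            if var in config.env_link:
                truth_env[var] = 0.0
        loc, scale = _ENV_UNITS[var]
        env_z[var] = np.maximum(loc + scale * _standardize(x), 0.0) if var not in (
            "temperature",
        ) else loc + scale * _standardize(x)

    samples = []
    total_cov = cov.sum(axis=1)
    for i in range(n_pools):
        env = {var: float(env_z[var][i]) for var in ENV_VARIABLES}
        samples.append(
            PopulationSample(
                sample_id=table.pools[i],
                station=f"ST{i + 1:03d}",
                depth="SUR",
                region=ARCTIC_REGIONS[i % len(ARCTIC_REGIONS)],
                latitude=float(rng.uniform(66.0, 89.0)),
                longitude=float(rng.uniform(-180.0, 180.0)),
                environment=env,
                mapped_read_count=int(total_cov[i]),
                total_read_count=int(total_cov[i]) * 1000,
            )
        )

    truth_selected = {
        ("sim_contig_1", int(positions[i])) for i in selected_idx
    }
    return SimulatedDataset(
        counts=table,
        truth_selected=truth_selected,
        truth_env_fractions=truth_env,
        samples=samples,
        true_frequencies=freqs,
        config=config,
    )


# ---------------------------------------------------------------------------
# toy genome + annotation + mutation list


@dataclass
class Mutation:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    context: str  # coding | UTR | intron | intergenic
    effect: str  # silent | missense | nonsense | none

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.alt) in TRANSITIONS


def _random_seq(rng, length):
    return "".join(rng.choice(_BASES, size=length))


def _random_cds(rng, n_codons):
    """ATG + random non-stop codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(("TAA", "TAG", "TGA")[int(rng.integers(3))])
    return "".join(codons)


_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _revcomp(s):
    return "".join(_RC[b] for b in reversed(s))


def simulate_annotation(
    n_genes: int,
    tstv_ratio: float,
    effect_mix: tuple,
    seed: int = 0,
    context_mix: tuple = (0.5, 0.3, 0.15, 0.05),
    n_mutations: int = 10000,
    genes_per_contig: int = 6,
):
    """Toy genome + GFF3-serialisable annotation + truth-labelled mutations.

    Parameters
    ----------
    n_genes
        Number of genes (> 0).
    tstv_ratio
        Requested transition:transversion ratio of the mutation list.
    effect_mix
        Proportions of (silent, missense, nonsense) among coding mutations;
        must sum to 1.
    context_mix
        Proportions of (coding, intergenic, UTR, intron) contexts.
    """
    if n_genes < 1:
        raise ParameterError("need at least one gene")
    if tstv_ratio <= 0:
        raise ParameterError("tstv_ratio must be positive")
    if abs(sum(effect_mix) - 1.0) > 1e-9 or any(x < 0 for x in effect_mix):
        raise ParameterError("effect_mix must be nonnegative and sum to 1")
    if abs(sum(context_mix) - 1.0) > 1e-9 or any(x < 0 for x in context_mix):
        raise ParameterError("context_mix must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)

    contig_seqs: dict = {}
    genes: list = []
    class_pos = {"coding": [], "UTR": [], "intron": [], "intergenic": []}

    for g in range(n_genes):
        contig = f"chr_{g // genes_per_contig + 1}"
        seq = contig_seqs.get(contig, "")
        # intergenic gap before the gene
        gap = int(rng.integers(200, 500))
        for k in range(gap):
            class_pos["intergenic"].append((contig, len(seq) + k))
        seq += _random_seq(rng, gap)

        strand = "+" if rng.random() < 0.5 else "-"
        u5 = _random_seq(rng, int(rng.integers(60, 150)))
        u3 = _random_seq(rng, int(rng.integers(60, 150)))
        n_exons = int(rng.integers(2, 5))
        cds = _random_cds(rng, int(rng.integers(40, 100)))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
        exon_parts = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
        introns = [_random_seq(rng, int(rng.integers(50, 120))) for _ in range(n_exons - 1)]

        # transcript-order elements
        elements = [(UTR5, u5)]
        for i, part in enumerate(exon_parts):
            elements.append((CODING, part))
            if i < len(introns):
                elements.append((INTRON, introns[i]))
        elements.append((UTR3, u3))
        if strand == "-":
            elements = [(kind, _revcomp(s)) for kind, s in reversed(elements)]

        features = []
        start0 = len(seq)
        for kind, s in elements:
            features.append((len(seq), len(seq) + len(s), kind))
            label = {CODING: "coding", UTR5: "UTR", UTR3: "UTR", INTRON: "intron"}[kind]
            for k in range(len(s)):
                class_pos[label].append((contig, len(seq) + k))
            seq += s
        contig_seqs[contig] = seq
        genes.append(Gene(f"gene_{g + 1:04d}", contig, strand, features))
        del start0

    # trailing gap so every contig ends intergenic
    for contig in list(contig_seqs):
        gap = int(rng.integers(200, 400))
        for k in range(gap):
            class_pos["intergenic"].append((contig, len(contig_seqs[contig]) + k))
        contig_seqs[contig] = contig_seqs[contig] + _random_seq(rng, gap)

    annotation = GeneAnnotation(
        contig_lengths={c: len(s) for c, s in contig_seqs.items()},
        genes=genes,
        sequences=contig_seqs,
    )

    from .variants import classify_effect  # local import to avoid cycle at load

    contexts = ("coding", "intergenic", "UTR", "intron")
    effects = ("silent", "missense", "nonsense")
    p_ts = tstv_ratio / (tstv_ratio + 1.0)
    mutations: list = []
    for _ in range(n_mutations):
        ctx = contexts[int(rng.choice(4, p=context_mix))]
        want_ts = bool(rng.random() < p_ts)
        if ctx != "coding":
            contig, pos0 = class_pos[ctx][int(rng.integers(len(class_pos[ctx])))]
            ref = contig_seqs[contig][pos0]
            if want_ts:
                alt = _TRANSITION_OF[ref]
            else:
                tv = [b for b in _BASES if b != ref and b != _TRANSITION_OF[ref]]
                alt = tv[int(rng.integers(2))]
            mutations.append(Mutation(contig, pos0 + 1, ref, alt, ctx, "none"))
            continue
        want_effect = effects[int(rng.choice(3, p=effect_mix))]
        placed = False
        for _try in range(500):
            contig, pos0 = class_pos["coding"][int(rng.integers(len(class_pos["coding"])))]
            ref = contig_seqs[contig][pos0]
            candidates = []
            for alt in _BASES:
                if alt == ref:
                    continue
                if (((ref, alt) in TRANSITIONS) != want_ts) and _try < 400:
                    continue
                eff = classify_effect(annotation, contig, pos0 + 1, ref, alt)
                if eff == want_effect:
                    candidates.append(alt)
            if candidates:
                alt = candidates[int(rng.integers(len(candidates)))]
                mutations.append(Mutation(contig, pos0 + 1, ref, alt, "coding", want_effect))
                placed = True
                break
        if not placed:  # pragma: no cover - effectively unreachable
            raise RuntimeError("could not place a coding mutation; enlarge the genome")
    return annotation, mutations


# ---------------------------------------------------------------------------
# coverage / identity profiles for the recruitment-QC stage


@dataclass
class CoverageProfile:
    depths: np.ndarray  # per reference position
    identities: np.ndarray  # per read, percent


def simulate_coverage_profile(
    genome_length: int,
    mean_depth: float,
    mode: str = "unimodal",
    seed: int = 0,
    dispersion: float = 0.3,
    bimodal_means: tuple | None = None,
    identity_center: float = 97.5,
    low_identity_fraction: float = 0.1,
    n_reads: int | None = None,
) -> CoverageProfile:
    """Per-base depth vector plus a read-identity histogram.

    ``unimodal`` draws depths from one negative binomial around
    ``mean_depth``; ``bimodal`` from a balanced mixture of two negative
    binomials with well-separated means (default ``mean_depth/6`` and
    ``mean_depth``), the signature of non-specific read recruitment.
    Identities concentrate around ``identity_center`` with a configurable
    low-identity tail.
    """
    if genome_length <= 0:
        raise ParameterError("genome_length must be positive")
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    if mode == "unimodal":
        depths = _draw_coverage(rng, mean_depth, dispersion, genome_length)
    elif mode == "bimodal":
        m1, m2 = bimodal_means if bimodal_means else (max(mean_depth / 6.0, 1.0), mean_depth)
        comp = rng.random(genome_length) < 0.5
        d1 = _draw_coverage(rng, m1, dispersion, genome_length)
        d2 = _draw_coverage(rng, m2, dispersion, genome_length)
        depths = np.where(comp, d1, d2)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if n_reads is None:
        n_reads = max(int(depths.sum() // 100), 10)
    n_low = int(round(low_identity_fraction * n_reads))
    core = np.clip(rng.normal(identity_center, 1.2, n_reads - n_low), 60.0, 100.0)
    tail = rng.uniform(70.0, 95.0, n_low)
    identities = rng.permutation(np.concatenate([core, tail]))
    return CoverageProfile(depths=depths.astype(np.int64), identities=identities)
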