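"""SNV calling from pooled counts and variant-landscape summaries.

A site is a single-nucleotide variant (SNV) when, pooling all admitted
populations, the minor-allele count reaches ``min_count`` and every
population's coverage lies inside ``[min_coverage, max_coverage]``
(min-covered-fraction-1 semantics: one underpowered pool excludes the site
everywhere, so densities are comparable across samples).  The landscape is
then characterised by SNV density per covered position, the
transition:transversion ratio, the genomic context of each variant
(coding / UTR / intron / intergenic) and, for coding variants, the amino
acid effect (silent / missense / nonsense).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .counts import BASE_ORDER, AlleleCountTable, ParameterError
from .fst import informative_mask

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GeneAnnotation",
    "SnvRecord",
    "call_snvs",
    "snv_density",
    "tstv_ratio",
    "classify_context",
    "classify_effect",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: feature kinds carried by genes; coordinates are 0-based half-open
CODING = "CDS"
UTR5 = "five_prime_UTR"
UTR3 = "three_prime_UTR"
INTRON = "intron"


class AnnotationError(ValueError):
    """Inconsistent gene annotation (e.g. CDS length not divisible by 3)."""


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    features: list  # [(start, end, kind)] 0-based half-open genomic coords

    def cds_intervals(self) -> list:
        iv = sorted((s, e) for s, e, k in self.features if k == CODING)
        return iv


@dataclass
class GeneAnnotation:
    """Toy-genome friendly annotation: contigs, stranded genes, sequences."""

    contig_lengths: dict
    genes: list = field(default_factory=list)
    sequences: dict | None = None
    _trees: dict | None = field(default=None, repr=False, compare=False)

    def _index(self) -> dict:
        if self._trees is None:
            trees: dict = {}
            for gene in self.genes:
                for start, end, kind in gene.features:
                    if end <= start:
                        continue
                    key = (gene.contig, kind)
                    trees.setdefault(key, IntervalTree()).addi(start, end, gene)
            self._trees = trees
        return self._trees

    def genes_overlapping(self, contig: str, pos0: int, kind: str) -> list:
        tree = self._index().get((contig, kind))
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos0)]

    def spliced_cds(self, gene: Gene) -> str:
        """CDS sequence in translation order (reverse-complemented on '-')."""
        if self.sequences is None:
            raise AnnotationError("annotation carries no sequences")
        seq = self.sequences[gene.contig]
        parts = [seq[s:e] for s, e in gene.cds_intervals()]
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        if len(cds) % 3 != 0:
            raise AnnotationError(f"CDS length of {gene.gene_id} not divisible by 3")
        return cds

    def cds_offset(self, gene: Gene, pos0: int) -> int:
        """Offset of a genomic position within the spliced, stranded CDS."""
        offset = 0
        total = 0
        found = False
        for s, e in gene.cds_intervals():
            if s <= pos0 < e:
                offset = total + (pos0 - s)
                found = True
            total += e - s
        if not found:
            raise ParameterError(f"position {pos0} not in CDS of {gene.gene_id}")
        if gene.strand == "-":
            offset = total - 1 - offset
        return offset


@dataclass
class SnvRecord:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    ref_counts: np.ndarray  # per pool
    alt_counts: np.ndarray
    coverage: np.ndarray
    context: str | None = None  # coding | UTR | intron | intergenic
    effect: str | None = None  # silent | missense | nonsense | none

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.alt) in TRANSITIONS


def call_snvs(
    counts: AlleleCountTable,
    min_count: int = 2,
    min_coverage: int = 4,
    max_coverage: int = 200,
    annotation: GeneAnnotation | None = None,
) -> list:
    """Call bi-allelic SNVs from a pooled count table.

    The alternative allele is the most frequent non-reference base over all
    pools, ties broken A < C < G < T; residual third/fourth alleles are
    ignored (logged in aggregate).  When an annotation is supplied, context
    and coding effect are filled in per record.
    """
    keep = informative_mask(counts, min_count, min_coverage, max_coverage)
    sub = counts.subset_loci(keep)
    alt = sub.alt_allele()
    ref_c = sub.ref_counts()
    alt_c = sub.alt_counts(alt)
    cov = sub.coverage()
    residual = int((cov - ref_c - alt_c).sum())
    if residual:
        logger.info("ignored %d reads on residual (3rd/4th) alleles", residual)

    records = []
    for i in range(sub.n_loci):
        rec = SnvRecord(
            contig=str(sub.contigs[i]),
            position=int(sub.positions[i]),
            ref=str(sub.ref[i]),
            alt=str(alt[i]),
            ref_counts=ref_c[i].copy(),
            alt_counts=alt_c[i].copy(),
            coverage=cov[i].copy(),
        )
        if annotation is not None:
            rec.context = classify_context(annotation, rec.contig, rec.position)
            rec.effect = (
                classify_effect(annotation, rec.contig, rec.position, rec.ref, rec.alt)
                if rec.context == "coding"
                else "none"
            )
        records.append(rec)
    return records


def snv_density(snvs, n_covered_positions: int) -> float:
    """Percent of covered positions that are SNVs (micro-diversity proxy)."""
    if n_covered_positions <= 0:
        raise ParameterError("n_covered_positions must be positive")
    n = len(snvs) if not np.isscalar(snvs) else int(snvs)
    return 100.0 * n / n_covered_positions


def tstv_ratio(snvs) -> float | None:
    """Transition:transversion ratio of a call set.

    Transitions are A<->G and C<->T.  Returns None (with a warning) when no
    transversion is present, in which case the ratio is undefined.
    """
    pairs = [(s.ref, s.alt) if isinstance(s, SnvRecord) else tuple(s) for s in snvs]
    ts = sum(1 for p in pairs if p in TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        logger.warning("no transversions observed; Ts/Tv undefined")
        return None
    return ts / tv


def classify_context(annotation: GeneAnnotation, contig: str, position: int) -> str:
    """Genomic context of a 1-based position.

    Exactly one of ``coding``, ``UTR``, ``intron``, ``intergenic``;
    overlapping features resolve with precedence coding > UTR > intron.
    """
    if contig not in annotation.contig_lengths:
        raise ParameterError(f"contig {contig!r} absent from annotation")
    pos0 = position - 1
    if not 0 <= pos0 < annotation.contig_lengths[contig]:
        raise ParameterError(f"position {position} beyond contig {contig!r}")
    if annotation.genes_overlapping(contig, pos0, CODING):
        return "coding"
    if annotation.genes_overlapping(contig, pos0, UTR5) or annotation.genes_overlapping(
        contig, pos0, UTR3
    ):
        return "UTR"
    if annotation.genes_overlapping(contig, pos0, INTRON):
        return "intron"
    return "intergenic"


def classify_effect(
    annotation: GeneAnnotation, contig: str, position: int, ref: str, alt: str
) -> str:
    """Amino-acid effect of a coding substitution.

    The alternative base is substituted into its codon (reverse-complemented
    for '-'-strand genes) and translated with the standard genetic code:
    same residue -> silent, gained stop -> nonsense, anything else
    (including a lost stop) -> missense.
    """
    pos0 = position - 1
    genes = annotation.genes_overlapping(contig, pos0, CODING)
    if not genes:
        raise ParameterError(f"{contig}:{position} is not in any CDS")
    gene = genes[0]
    cds = annotation.spliced_cds(gene)
    offset = annotation.cds_offset(gene, pos0)
    base = alt if gene.strand == "+" else _COMPLEMENT[alt]
    ref_base = ref if gene.strand == "+" else _COMPLEMENT[ref]
    if cds[offset] != ref_base:
        logger.warning(
            "reference mismatch at %s:%d (annotation %s, variant %s)",
            contig,
            position,
            cds[offset],
            ref_base,
        )
    codon_i = offset // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    mutated = codon[: offset % 3] + base + codon[offset % 3 + 1 :]
    table = CodonTable.unambiguous_dna_by_id[1]
    aa_ref = "*" if codon in table.stop_codons else table.forward_table[codon]
    aa_alt = "*" if mutated in table.stop_codons else table.forward_table[mutated]
    if aa_alt == aa_ref:
        return "silent"
    if aa_alt == "*":
        return "nonsense"
    return "missense"  # includes stop-loss
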