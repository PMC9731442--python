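"""Readers and writers for the pipeline's on-disk formats.

Formats: PoPoolation2-style sync count tables, VCF v4.2 call sets, GFF3
annotation, FASTA toy genomes, TSV sample metadata and matrices, JSON
reports.  Internal coordinates are 0-based half-open; sync, VCF and GFF3
are serialised 1-based per their standards.  Readers reject malformed input
with the offending line number rather than coercing it.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from .counts import SYNC_ORDER, AlleleCountTable, ParameterError
from .samples import ENV_VARIABLES, PopulationSample
from .variants import CODING, INTRON, UTR3, UTR5, Gene, GeneAnnotation, SnvRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_sync",
    "write_sync",
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
    "write_samples_tsv",
    "read_samples_tsv",
]


class SyncParseError(ValueError):
    """Malformed sync input, annotated with the 1-based line number."""


def read_sync(path) -> AlleleCountTable:
    """Parse a sync file: contig, 1-based position, reference base, then one
    colon-joined A:T:C:G:N:del count field per pool."""
    contigs, positions, refs, rows = [], [], [], []
    n_pools = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"{path}:{lineno}: expected at least 4 tab-separated fields, got {len(fields)}"
                )
            if n_pools is None:
                n_pools = len(fields) - 3
            elif len(fields) - 3 != n_pools:
                raise SyncParseError(
                    f"{path}:{lineno}: inconsistent pool count "
                    f"({len(fields) - 3} vs {n_pools})"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise SyncParseError(f"{path}:{lineno}: bad position {fields[1]!r}") from exc
            pools = []
            for field in fields[3:]:
                parts = field.split(":")
                if len(parts) != len(SYNC_ORDER):
                    raise SyncParseError(
                        f"{path}:{lineno}: count field {field!r} must have "
                        f"{len(SYNC_ORDER)} colon-separated integers"
                    )
                try:
                    pools.append([int(x) for x in parts])
                except ValueError as exc:
                    raise SyncParseError(
                        f"{path}:{lineno}: non-integer count in {field!r}"
                    ) from exc
            contigs.append(fields[0])
            positions.append(pos)
            refs.append(fields[2].upper())
            rows.append(pools)
    if not rows:
        warnings.warn(f"{path}: empty sync file", stacklevel=2)
        return AlleleCountTable(
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=object),
            np.zeros((0, n_pools or 1, len(SYNC_ORDER)), dtype=np.int64),
        )
    return AlleleCountTable(
        np.array(contigs, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(rows, dtype=np.int64),
    )


def write_sync(table: AlleleCountTable, path) -> None:
    with open(path, "w") as handle:
        for i in range(table.n_loci):
            cols = [
                str(table.contigs[i]),
                str(int(table.positions[i])),
                str(table.ref[i]),
            ]
            for j in range(table.n_pools):
                cols.append(":".join(str(int(c)) for c in table.counts[i, j]))
            handle.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(snvs: list, path, contig_lengths: dict | None = None, pools: list | None = None) -> None:
    """Minimal VCF v4.2 with per-pool depth (DP) and allele depth (AD).

    Records must arrive sorted by contig then position.
    """
    last = {}
    for rec in snvs:
        if rec.contig in last and rec.position <= last[rec.contig]:
            raise ParameterError(
                f"unsorted VCF input at {rec.contig}:{rec.position}"
            )
        last[rec.contig] = rec.position
    if contig_lengths is None:
        contig_lengths = {}
        for rec in snvs:
            contig_lengths[rec.contig] = max(contig_lengths.get(rec.contig, 0), rec.position)
    if pools is None:
        pools = (
            [f"pool_{i + 1:02d}" for i in range(len(snvs[0].coverage))] if snvs else []
        )
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("##source=magpop\n")
        for contig, length in contig_lengths.items():
            handle.write(f"##contig=<ID={contig},length={length}>\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        handle.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Genomic context">\n')
        handle.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Pool depth">\n')
        handle.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt allele depths">\n'
        )
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools) + "\n"
        )
        for rec in snvs:
            info = f"DP={int(rec.coverage.sum())}"
            info += f";CTX={rec.context if rec.context else 'NA'}"
            info += f";EFF={rec.effect if rec.effect else 'NA'}"
            samples = [
                f"{int(dp)}:{int(r)},{int(a)}"
                for dp, r, a in zip(rec.coverage, rec.ref_counts, rec.alt_counts)
            ]
            handle.write(
                f"{rec.contig}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}"
                f"\tDP:AD\t" + "\t".join(samples) + "\n"
            )


def read_vcf(path) -> list:
    """Read a per-pool DP/AD call set (round-trips :func:`write_vcf`)."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        dp = np.asarray(v.format("DP")).reshape(-1)
        ad = np.asarray(v.format("AD"))
        ctx = v.INFO.get("CTX", "NA")
        eff = v.INFO.get("EFF", "NA")
        records.append(
            SnvRecord(
                contig=v.CHROM,
                position=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                ref_counts=ad[:, 0].astype(np.int64),
                alt_counts=ad[:, 1].astype(np.int64),
                coverage=dp.astype(np.int64),
                context=None if ctx == "NA" else ctx,
                effect=None if eff == "NA" else eff,
            )
        )
    return records


# ---------------------------------------------------------------------------
# GFF3 / FASTA

_KIND_TO_SO = {
    UTR5: "five_prime_UTR",
    UTR3: "three_prime_UTR",
    CODING: "CDS",
    INTRON: "intron",
}
_SO_TO_KIND = {v: k for k, v in _KIND_TO_SO.items()}


def write_gff3(annotation: GeneAnnotation, path) -> None:
    """GFF3 with gene/mRNA parents and UTR/CDS/intron children (1-based,
    inclusive ends; CDS phase computed in translation order)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for contig, length in annotation.contig_lengths.items():
            handle.write(f"##sequence-region {contig} 1 {length}\n")
        for gene in annotation.genes:
            start = min(s for s, _e, _k in gene.features) + 1
            end = max(e for _s, e, _k in gene.features)
            base = f"{gene.contig}\tmagpop"
            handle.write(
                f"{base}\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            mrna = f"{gene.gene_id}.t1"
            handle.write(
                f"{base}\tmRNA\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={mrna};Parent={gene.gene_id}\n"
            )
            cds = gene.cds_intervals()
            ordered = cds if gene.strand == "+" else cds[::-1]
            phases = {}
            acc = 0
            for s, e in ordered:
                phases[(s, e)] = (3 - acc % 3) % 3
                acc += e - s
            for s, e, kind in sorted(gene.features):
                phase = phases.get((s, e), ".") if kind == CODING else "."
                handle.write(
                    f"{base}\t{_KIND_TO_SO[kind]}\t{s + 1}\t{e}\t.\t{gene.strand}\t"
                    f"{phase}\tID={gene.gene_id}.{_KIND_TO_SO[kind]}.{s + 1};Parent={mrna}\n"
                )


def read_gff3(path, sequences: dict | None = None) -> GeneAnnotation:
    """Load a GFF3 annotation (via gffutils) into :class:`GeneAnnotation`."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    contig_lengths: dict = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("##sequence-region"):
                _tag, contig, _start, end = line.split()
                contig_lengths[contig] = int(end)
    genes = []
    for g in db.features_of_type("gene"):
        features = []
        for child in db.children(g, level=None):
            if child.featuretype in _SO_TO_KIND:
                features.append(
                    (child.start - 1, child.end, _SO_TO_KIND[child.featuretype])
                )
        genes.append(Gene(g.id, g.seqid, g.strand, sorted(features)))
        contig_lengths.setdefault(g.seqid, max(e for _s, e, _k in features))
    return GeneAnnotation(
        contig_lengths=contig_lengths, genes=genes, sequences=sequences
    )


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# sample metadata


def write_samples_tsv(samples: list, path) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "station": s.station,
            "depth": s.depth,
            "region": s.region,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "mapped_read_count": s.mapped_read_count,
            "total_read_count": s.total_read_count,
        }
        row.update({v: s.environment.get(v) for v in ENV_VARIABLES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path, column_map: dict | None = None) -> list:
    """Read sample metadata; ``column_map`` renames provider-specific
    column names (e.g. PANGAEA export headers) onto the canonical ones."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    samples = []
    for _, row in df.iterrows():
        env = {v: float(row[v]) for v in ENV_VARIABLES if v in df.columns and pd.notna(row[v])}
        samples.append(
            PopulationSample(
                sample_id=str(row["sample_id"]),
                station=str(row.get("station", "")),
                depth=str(row.get("depth", "")),
                region=None if pd.isna(row.get("region")) else str(row.get("region")),
                latitude=None if pd.isna(row.get("latitude")) else float(row["latitude"]),
                longitude=None if pd.isna(row.get("longitude")) else float(row["longitude"]),
                environment=env,
                mapped_read_count=int(row.get("mapped_read_count", 0) or 0),
                total_read_count=int(row.get("total_read_count", 0) or 0),
            )
        )
    return samples


def write_json_report(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.DataFrame, pd.Series)):
            return json.loads(o.to_json())
        raise TypeError(type(o).__name__)

    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, default=default)
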