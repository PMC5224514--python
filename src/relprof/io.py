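"""Readers and writers for the standard formats the pipeline touches.

FASTA is read with Biopython, GFF3 with gffutils (in-memory db), SAM with
pysam.  Internal coordinates are 0-based half-open; GFF3 is converted on
ingest.  Cross-checks between annotation, operon table and genome are
performed here so downstream modules can assume consistent inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .transcriptome import GeneModel

log = logging.getLogger(__name__)


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load contigs as uppercase strings indexed by name."""
    from Bio import SeqIO

    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences in {fasta_path}")
    return genome


@dataclass
class AnnotationSet:
    """CDS annotation plus the operon table."""

    genes: list[GeneModel]
    operons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["operon_id", "gene_id", "position"]
        )
    )

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("gene ids are not unique")
        for op_id, grp in self.operons.groupby("operon_id"):
            pos = sorted(grp["position"])
            if pos != list(range(1, len(pos) + 1)):
                raise ValueError(f"operon {op_id}: positions not contiguous from 1")

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def load_annotation(
    gff_path: str | Path, operon_tsv: str | Path | None = None
) -> AnnotationSet:
    """Load CDS features from GFF3 (1-based inclusive -> 0-based half-open)
    and attach the operon table, cross-checking the two.

    Genes whose CDS length is not a multiple of 3 are excluded with a
    warning; operon rows referencing unknown genes are skipped with a
    warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("gene_id", feat.attributes.get("ID", [feat.id]))[0]
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if (end - start) % 3:
            log.warning("%s: CDS length %d not divisible by 3; excluded", gene_id, end - start)
            continue
        op = feat.attributes.get("operon_id", [None])[0]
        op_pos = feat.attributes.get("operon_position", [None])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                operon_id=op,
                operon_position=int(op_pos) if op_pos is not None else None,
            )
        )
    if not genes:
        raise ValueError(f"no CDS features in {gff_path}")

    if operon_tsv is not None:
        operons = pd.read_csv(operon_tsv, sep="\t")
        known = {g.gene_id for g in genes}
        bad = ~operons["gene_id"].isin(known)
        if bad.any():
            for gid in operons.loc[bad, "gene_id"]:
                log.warning("operon table references unknown gene %s; skipped", gid)
            operons = operons[~bad].reset_index(drop=True)
    else:
        operons = pd.DataFrame(columns=["operon_id", "gene_id", "position"])
    return AnnotationSet(genes=genes, operons=operons)


@dataclass
class SimpleRead:
    contig: str
    strand: str
    start: int  # 0-based leftmost
    end: int  # exclusive
    mapq: int = 255


class AlignedReadSet:
    """Materialised set of accepted alignments with ingest statistics."""

    def __init__(self, reads: list[SimpleRead], n_unmapped: int = 0, n_filtered: int = 0):
        self.reads = reads
        self.n_unmapped = n_unmapped
        self.n_filtered = n_filtered

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def load_alignments(
    sam_path: str | Path,
    unique_only: bool = True,
    min_mapq: int = 10,
    genome: dict[str, str] | None = None,
) -> AlignedReadSet:
    """Load single-end alignments from SAM/BAM.

    Unmapped records are dropped; with ``unique_only`` secondary,
    supplementary and low-MAPQ records are dropped too (uniqueness is judged
    from SAM flags/MAPQ, not realigned).  If ``genome`` is given, the @SQ
    contigs must match it.
    """
    import pysam

    reads: list[SimpleRead] = []
    n_unmapped = n_filtered = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        if genome is not None:
            for sq in fh.header.get("SQ", []):
                name = sq["SN"]
                if name not in genome:
                    raise ValueError(f"SAM contig {name} absent from genome")
                if sq["LN"] != len(genome[name]):
                    raise ValueError(f"SAM contig {name} length mismatch with genome")
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if unique_only and (
                rec.is_secondary or rec.is_supplementary or rec.mapping_quality < min_mapq
            ):
                n_filtered += 1
                continue
            reads.append(
                SimpleRead(
                    contig=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start,
                    end=rec.reference_end,
                    mapq=rec.mapping_quality,
                )
            )
    log.info(
        "%s: %d accepted, %d unmapped, %d non-unique/low-MAPQ dropped",
        sam_path, len(reads), n_unmapped, n_filtered,
    )
    return AlignedReadSet(reads, n_unmapped, n_filtered)


def write_bedgraph(
    counts: dict[tuple[str, str], np.ndarray], path_prefix: str | Path
) -> list[Path]:
    """Write one BedGraph file per strand (``<prefix>.plus.bedgraph`` /
    ``<prefix>.minus.bedgraph``), runs of equal nonzero counts merged."""
    paths = []
    for strand, label in (("+", "plus"), ("-", "minus")):
        path = Path(f"{path_prefix}.{label}.bedgraph")
        with open(path, "w") as fh:
            for (contig, s), arr in sorted(counts.items()):
                if s != strand:
                    continue
                nz = np.flatnonzero(arr)
                if nz.size == 0:
                    continue
                run_start = nz[0]
                prev = nz[0]
                val = arr[nz[0]]
                for i in nz[1:]:
                    if i == prev + 1 and arr[i] == val:
                        prev = i
                        continue
                    fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{val}\n")
                    run_start = prev = i
                    val = arr[i]
                fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{val}\n")
        paths.append(path)
    return paths
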