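"""Synthetic bacterial transcriptomes for footprint simulation.

The generator builds a single-contig genome carrying a configurable number of
protein-coding genes organised into operons, with per-transcript UTRs and,
optionally, one gene carrying a programmed frameshift site (a prfB-like
construct: an in-frame stop at a chosen codon with an open reading frame
continuing in the shifted frame).  The object returned is the ground truth
against which every downstream analysis is tested.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive per the format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameshiftSpec:
    """A programmed frameshift site inside one gene.

    For a +1 shift the gene carries an in-frame stop at ``codon_index``
    (1-based) and an open reading frame in the +1 frame starting at
    nucleotide ``3*(codon_index-1)+1`` of the CDS; for a -1 shift no stop is
    placed and the -1 frame opens at ``3*(codon_index-1)-1``.
    """

    codon_index: int = 28
    direction: int = 1
    downstream_codons: int = 60

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("frameshift direction must be +1 or -1")
        if self.codon_index < 3:
            raise ValueError("frameshift codon_index must be >= 3")
        if self.downstream_codons < 50:
            raise ValueError("shifted-frame ORF must continue >= 50 codons")

    @property
    def shift_site_nt(self) -> int:
        """CDS offset of the A-site codon first nt at which the shift occurs."""
        return 3 * (self.codon_index - 1)

    @property
    def shifted_orf_start_nt(self) -> int:
        """CDS offset of the first shifted-frame codon."""
        return self.shift_site_nt + self.direction


@dataclass
class GeneModel:
    """One annotated CDS (genomic, 0-based half-open)."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    operon_id: str | None = None
    operon_position: int | None = None
    frameshift: FrameshiftSpec | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if (self.end - self.start) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def cds_len(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3


@dataclass
class SyntheticTranscriptome:
    """Genome + annotation ground truth produced by :func:`generate_transcriptome`."""

    genome: dict[str, str]
    genes: list[GeneModel]
    operons: list[list[str]]
    utr5_len: int = 30
    utr3_len: int = 90
    _by_id: dict[str, GeneModel] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    # ---- coordinate helpers -------------------------------------------------
    def to_genomic(self, gene: GeneModel, t: int) -> int:
        """Genomic position of CDS transcript-offset ``t`` (0 = first nt of start codon)."""
        if gene.strand == "+":
            return gene.start + t
        return gene.end - 1 - t

    def to_transcript(self, gene: GeneModel, pos: int) -> int:
        if gene.strand == "+":
            return pos - gene.start
        return gene.end - 1 - pos

    def cds_seq(self, gene: GeneModel) -> str:
        raw = self.genome[gene.contig][gene.start : gene.end]
        return raw if gene.strand == "+" else revcomp(raw)

    def transcript_nt(self, gene: GeneModel, t: int) -> str:
        """Transcript-orientation base at CDS offset ``t`` (may reach into UTRs)."""
        pos = self.to_genomic(gene, t)
        base = self.genome[gene.contig][pos]
        return base if gene.strand == "+" else base.translate(_COMPLEMENT)

    def transcript_bounds(self, gene: GeneModel) -> tuple[int, int]:
        """CDS-offset range [lo, hi) covered by the transcript including UTRs."""
        return -self.utr5_len, gene.cds_len + self.utr3_len

    # ---- writers ------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="synthetic")
            for name, seq in self.genome.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.genome.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                attrs = [f"ID={g.gene_id}", f"gene_id={g.gene_id}"]
                if g.operon_id is not None:
                    attrs.append(f"operon_id={g.operon_id}")
                    attrs.append(f"operon_position={g.operon_position}")
                fh.write(
                    "\t".join(
                        [
                            g.contig,
                            "relprof_sim",
                            "CDS",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )

    def write_operon_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for i, op in enumerate(self.operons):
            for pos, gid in enumerate(op, start=1):
                rows.append({"operon_id": f"op{i + 1:03d}", "gene_id": gid, "position": pos})
        pd.DataFrame(rows, columns=["operon_id", "gene_id", "position"]).to_csv(
            path, sep="\t", index=False
        )


def gene_cds_seq(genome: dict[str, str], gene: GeneModel) -> str:
    """CDS sequence of ``gene`` in transcript orientation."""
    raw = genome[gene.contig][gene.start : gene.end]
    return raw if gene.strand == "+" else revcomp(raw)


def _random_codons(rng: np.random.Generator, n: int, p: np.ndarray) -> list[str]:
    idx = rng.choice(len(SENSE_CODONS), size=n, p=p)
    return [SENSE_CODONS[i] for i in idx]


def _frameshift_cds(
    rng: np.random.Generator, spec: FrameshiftSpec, p: np.ndarray
) -> str:
    """Build a CDS with an open shifted-frame ORF downstream of the shift site.

    Shifted-frame codons are drawn from sense codons carrying no C at their
    second or third position, so that RelE cleavage downstream of the shift
    stays after the second nucleotide of the decoded codon and its products
    are neither NNC-cut nor NNC-shifted away from the shifted frame; the
    construct then shows the clean dominant-position transition seen at
    prfB.
    """
    non_nnc = [cod for cod in SENSE_CODONS if "C" not in cod[1:]]

    def _shifted_codons(n: int) -> str:
        return "".join(non_nnc[i] for i in rng.integers(len(non_nnc), size=n))

    c = spec.codon_index
    seq: list[str] = ["ATG"] + _random_codons(rng, c - 2, p)
    if spec.direction == 1:
        # in-frame stop at codon c; +1 ORF starts 1 nt into it
        seq.append("TGA")
        nts = list("".join(seq))
        # first +1-frame codon = "GA" + next base (GAA/GAG/GAT: sense, non-NNC)
        nts.append(str(rng.choice(["A", "G", "T"])))
        nts.extend(_shifted_codons(spec.downstream_codons - 1))
        nts.extend("TAA")  # shifted-frame stop
    else:
        nts = list("".join(seq))
        # -1 ORF starts at the last nt of codon c-1; complete that codon as sense
        first = nts[-1]
        choices = [cod for cod in non_nnc if cod[0] == first]
        nts.extend(choices[rng.integers(len(choices))][1:])
        nts.extend(_shifted_codons(spec.downstream_codons - 1))
        nts.extend("TAA")
    # pad to a multiple of 3 and close the annotated frame with a stop
    pad = (-(len(nts) + 3)) % 3
    nts.extend(str(rng.choice(list(_BASES))) for _ in range(pad))
    nts.extend("TAA")
    return "".join(nts)


def _partition_operons(
    rng: np.random.Generator, n_genes: int, n_operons: int
) -> list[int]:
    if n_operons > n_genes:
        raise ValueError("n_operons cannot exceed n_genes")
    sizes = np.ones(n_operons, dtype=int)
    for _ in range(n_genes - n_operons):
        sizes[rng.integers(n_operons)] += 1
    return sizes.tolist()


def generate_transcriptome(
    n_genes: int = 50,
    n_operons: int | None = None,
    gene_length_range: tuple[int, int] = (350, 450),
    codon_usage: dict[str, float] | None = None,
    frameshift_spec: FrameshiftSpec | None = None,
    rng_seed: int = 0,
    utr5_len: int = 30,
    utr3_len: int = 90,
    contig: str = "synChr",
    intergenic_len: int = 150,
    intra_operon_gap: int = 80,
) -> SyntheticTranscriptome:
    """Generate a deterministic synthetic transcriptome.

    Parameters
    ----------
    n_genes : total gene count (the frameshift gene, if requested, is the last).
    n_operons : operon count; defaults to ``max(1, n_genes // 3)``.
    gene_length_range : CDS length range in codons (inclusive).
    codon_usage : probability per sense codon (uniform over the 61 by default).
    frameshift_spec : if given, the last gene is a frameshift construct.
    rng_seed : mandatory seed; identical seeds give byte-identical output.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_operons is None:
        n_operons = max(1, n_genes // 3)
    rng = np.random.default_rng(rng_seed)

    if codon_usage is None:
        p = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        p = np.array([codon_usage.get(c, 0.0) for c in SENSE_CODONS], dtype=float)
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("codon usage must sum to 1 over the 61 sense codons")
        p = p / p.sum()

    # CDS sequences (transcript orientation)
    lo, hi = gene_length_range
    cds_seqs: list[str] = []
    specs: list[FrameshiftSpec | None] = []
    for i in range(n_genes):
        if frameshift_spec is not None and i == n_genes - 1:
            cds_seqs.append(_frameshift_cds(rng, frameshift_spec, p))
            specs.append(frameshift_spec)
        else:
            n_cod = int(rng.integers(lo, hi + 1))
            body = ["ATG"] + _random_codons(rng, n_cod - 2, p) + [
                STOP_CODONS[rng.integers(3)]
            ]
            cds_seqs.append("".join(body))
            specs.append(None)

    sizes = _partition_operons(rng, n_genes, n_operons)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in sizes]

    # lay operons left to right along the contig
    genome_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    operons: list[list[str]] = []
    gene_idx = 0
    for op_i, (size, strand) in enumerate(zip(sizes, strands)):
        op_id = f"op{op_i + 1:03d}"
        spacer = "".join(rng.choice(list(_BASES), size=intergenic_len))
        genome_parts.append(spacer)
        cursor += intergenic_len
        members = list(range(gene_idx, gene_idx + size))
        gene_idx += size
        # on '-' operons the genomically-leftmost gene is the transcriptionally last
        layout = members if strand == "+" else members[::-1]
        op_gene_ids = [f"gene{m + 1:04d}" for m in members]
        for j, m in enumerate(layout):
            seq = cds_seqs[m]
            start, end = cursor, cursor + len(seq)
            genome_parts.append(seq if strand == "+" else revcomp(seq))
            cursor = end
            pos_in_op = members.index(m) + 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{m + 1:04d}",
                    contig=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    operon_id=op_id,
                    operon_position=pos_in_op,
                    frameshift=specs[m],
                )
            )
            if j < size - 1:
                gap = "".join(rng.choice(list(_BASES), size=intra_operon_gap))
                genome_parts.append(gap)
                cursor += intra_operon_gap
        operons.append(op_gene_ids)
    tail = "".join(rng.choice(list(_BASES), size=intergenic_len))
    genome_parts.append(tail)

    genome = {contig: "".join(genome_parts)}
    genes.sort(key=lambda g: g.start)
    return SyntheticTranscriptome(
        genome=genome,
        genes=genes,
        operons=operons,
        utr5_len=utr5_len,
        utr3_len=utr3_len,
    )
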