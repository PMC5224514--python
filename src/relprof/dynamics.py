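"""Stochastic ribosome dynamics under mRNA cleavage, rescue and initiation.

The in vivo model is a continuous-time Markov chain simulated exactly
(event-driven, per mRNA copy): ribosomes initiate at the start codon when
the first codons are clear, elongate codon by codon under steric exclusion,
are cleaved in the A site by RelE (which truncates the message at the cut
and stalls the ribosome), and stalled ribosomes are removed by rescue
(tmRNA/ArfA, lumped into one rate).  The truncated 5' fragment keeps its
start codon and remains initiable, so repeated cycles of cleavage, rescue
and re-initiation progressively concentrate ribosomes toward the 5' end of
genes — the mechanism behind the 5' polarity seen in vivo.

IN_VITRO mode represents a lysate digestion: elongation and initiation are
frozen, so the supplied occupancy snapshot is returned unchanged and only
the nuclease geometry acts on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .transcriptome import STOP_CODONS, GeneModel, SyntheticTranscriptome

#: minimal A-site spacing between adjacent ribosomes on one mRNA (10 codons)
STERIC_NT = 30


class SimMode(str, Enum):
    IN_VIVO = "IN_VIVO"
    IN_VITRO = "IN_VITRO"


@dataclass
class RiboSimConfig:
    """Kinetic parameters of the cleavage/rescue/initiation cycle.

    Rates are per ribosome (or per mRNA for ``k_init``) per second.
    """

    mode: SimMode = SimMode.IN_VIVO
    k_init: float = 0.2
    k_elong: float = 10.0
    k_cleave: float = 0.3
    k_rescue: float = 0.5
    n_mrna_copies: int = 5
    sim_time: float = 150.0
    read_length_window: tuple[int, int] = (20, 40)
    p_occupied_Asite: float = 0.1
    #: observe each mRNA copy at an age drawn uniformly from [0, sim_time]
    #: instead of exactly sim_time -- models continuous transcription during
    #: an induction window, giving a mixture of young (fully covered) and
    #: old (5'-truncated) messages
    age_mixture: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.mode = SimMode(self.mode)
        for name in ("k_init", "k_elong", "k_cleave", "k_rescue", "sim_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_occupied_Asite <= 1:
            raise ValueError("p_occupied_Asite must lie in [0, 1]")
        if self.n_mrna_copies < 1:
            raise ValueError("n_mrna_copies must be >= 1")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        if self.mode is SimMode.IN_VITRO:
            # frozen lysate: no initiation, no elongation
            self.k_init = 0.0
            self.k_elong = 0.0


@dataclass
class Ribosome:
    """One ribosome; ``asite_nt`` is the CDS offset of its A-site codon first nt."""

    asite_nt: int
    a_site_occupied: bool = False
    stalled: bool = False
    cleaved: bool = False


@dataclass
class RibosomeSnapshot:
    """State of one mRNA copy at observation time."""

    gene_id: str
    ribosomes: list[Ribosome] = field(default_factory=list)
    truncation_nt: int | None = None  # exclusive CDS offset of the 3' cut, if any

    def validate(self, gene: GeneModel) -> None:
        pos = sorted(r.asite_nt for r in self.ribosomes)
        for a, b in zip(pos, pos[1:]):
            if b - a < STERIC_NT:
                raise ValueError("ribosomes closer than the steric limit")
        for r in self.ribosomes:
            if not 0 <= r.asite_nt <= gene.cds_len - 1:
                raise ValueError("A site outside the ORF")


def _asite_choices(gene: GeneModel, include_terminal: bool = False) -> np.ndarray:
    """Valid A-site first-nt offsets for elongating ribosomes on this gene."""
    if gene.frameshift is None:
        hi = gene.cds_len - 3 if include_terminal else gene.cds_len - 6
        return np.arange(6, hi + 1, 3)
    fs = gene.frameshift
    up = np.arange(6, fs.shift_site_nt + 1, 3)
    s0 = fs.shifted_orf_start_nt
    down = s0 + 3 * np.arange(fs.downstream_codons)
    return np.concatenate([up, down])


def place_ribosomes(
    tx: SyntheticTranscriptome,
    n_per_gene: int = 200,
    f_initiation: float = 0.2,
    f_termination: float = 0.0,
    p_occupied: float = 0.0,
    rng: np.random.Generator | int | None = None,
    genes: list[str] | None = None,
) -> list[RibosomeSnapshot]:
    """Draw a static ribosome occupancy: a mix of initiation complexes (start
    codon in P site, codon 2 in A site), termination complexes (stop codon in
    A site) and uniformly placed elongating ribosomes.

    Ribosomes are packed greedily onto as many mRNA copies as the 10-codon
    steric limit requires, so every returned snapshot is physically valid.
    """
    if not 0 <= f_initiation + f_termination <= 1:
        raise ValueError("initiation/termination fractions must sum to <= 1")
    rng = np.random.default_rng(rng)
    snapshots: list[RibosomeSnapshot] = []
    gene_list = tx.genes if genes is None else [tx.gene(g) for g in genes]
    for gene in gene_list:
        choices = _asite_choices(gene)
        u = rng.random(n_per_gene)
        asites = np.where(
            u < f_initiation,
            3,
            np.where(
                u < f_initiation + f_termination,
                gene.cds_len - 3,
                rng.choice(choices, size=n_per_gene),
            ),
        )
        occupied = rng.random(n_per_gene) < p_occupied
        # greedy packing into steric-valid mRNA copies
        order = np.argsort(asites, kind="stable")
        copies: list[RibosomeSnapshot] = []
        tails: list[int] = []
        for i in order:
            a = int(asites[i])
            rib = Ribosome(asite_nt=a, a_site_occupied=bool(occupied[i]))
            for c, tail in enumerate(tails):
                if a - tail >= STERIC_NT:
                    copies[c].ribosomes.append(rib)
                    tails[c] = a
                    break
            else:
                copies.append(RibosomeSnapshot(gene_id=gene.gene_id, ribosomes=[rib]))
                tails.append(a)
        snapshots.extend(copies)
    return snapshots


def _decoded_codon(cds: str, asite: int) -> str:
    return cds[asite : asite + 3]


def simulate_dynamics(
    tx: SyntheticTranscriptome,
    config: RiboSimConfig,
    initial: list[RibosomeSnapshot] | None = None,
    genes: list[str] | None = None,
) -> list[RibosomeSnapshot]:
    """Run the cleavage/rescue/initiation model and return one snapshot per
    mRNA copy at ``config.sim_time``.

    In IN_VITRO mode the initial occupancy (``initial``, or a default uniform
    placement) is returned unchanged: frozen ribosomes are invariant under
    simulation time.
    """
    rng = np.random.default_rng(config.rng_seed)
    gene_list = tx.genes if genes is None else [tx.gene(g) for g in genes]

    if config.mode is SimMode.IN_VITRO:
        if initial is None:
            initial = place_ribosomes(
                tx,
                f_initiation=0.2,
                p_occupied=config.p_occupied_Asite,
                rng=rng,
                genes=[g.gene_id for g in gene_list],
            )
        return initial

    # group genes into their transcription units (polycistronic mRNAs);
    # genes outside any listed operon become monocistronic messages
    wanted = {g.gene_id for g in gene_list}
    units: list[list[GeneModel]] = []
    in_operon: set[str] = set()
    for op in tx.operons:
        members = [tx.gene(g) for g in op if g in wanted]
        if members:
            units.append(members)
            in_operon.update(g.gene_id for g in members)
    units.extend([[g] for g in gene_list if g.gene_id not in in_operon])

    snapshots: list[RibosomeSnapshot] = []
    for genes_tu in units:
        for _copy in range(config.n_mrna_copies):
            snapshots.extend(_simulate_transcript(tx, genes_tu, config, rng))
    return snapshots


def _simulate_transcript(
    tx: SyntheticTranscriptome,
    genes_tu: list[GeneModel],
    config: RiboSimConfig,
    rng: np.random.Generator,
) -> list[RibosomeSnapshot]:
    """One polycistronic mRNA copy: cistrons initiate independently, but a
    RelE cut anywhere truncates the message, so every cistron downstream of
    the 5'-most cut leaves the initiable pool (its ribosomes already past
    the cut run off to completion on the released fragment)."""
    cds = [tx.cds_seq(g) for g in genes_tu]
    shift = [
        g.frameshift.shift_site_nt if g.frameshift is not None else None
        for g in genes_tu
    ]
    ribs: list[list[Ribosome]] = [[] for _ in genes_tu]
    trunc: tuple[int, int] | None = None  # (cistron index, exclusive nt offset)
    t_end = (
        rng.uniform(0.0, config.sim_time) if config.age_mixture else config.sim_time
    )

    def limit(i: int) -> int:
        if trunc is None or i < trunc[0]:
            return genes_tu[i].cds_len
        if i == trunc[0]:
            return trunc[1]
        return 0  # cistron entirely downstream of the cut

    def past_cut(i: int, a: int) -> bool:
        return trunc is not None and (i > trunc[0] or (i == trunc[0] and a >= trunc[1]))

    t = 0.0
    while True:
        initiable = []
        if config.k_init > 0:
            for i, g in enumerate(genes_tu):
                if limit(i) >= 6 and (
                    not ribs[i] or ribs[i][0].asite_nt >= 3 + STERIC_NT
                ):
                    initiable.append(i)
        active = [(i, r) for i, rr in enumerate(ribs) for r in rr if not r.stalled]
        stalled = [(i, r) for i, rr in enumerate(ribs) for r in rr if r.stalled]
        cleavable = [(i, r) for i, r in active if not r.a_site_occupied]
        r_init = config.k_init * len(initiable)
        r_elong = config.k_elong * len(active)
        r_cleave = config.k_cleave * len(cleavable)
        r_rescue = config.k_rescue * len(stalled)
        total = r_init + r_elong + r_cleave + r_rescue
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        if u < r_init:
            i = initiable[int(u / config.k_init)]
            ribs[i].insert(
                0,
                Ribosome(
                    asite_nt=3,
                    a_site_occupied=rng.random() < config.p_occupied_Asite,
                ),
            )
        elif u < r_init + r_elong:
            i, r = active[int((u - r_init) / config.k_elong)]
            pos = ribs[i].index(r)
            if shift[i] is not None and r.asite_nt == shift[i]:
                nxt = r.asite_nt + genes_tu[i].frameshift.direction
            elif _decoded_codon(cds[i], r.asite_nt) in STOP_CODONS:
                ribs[i].pop(pos)  # termination: ribosome released
                continue
            else:
                nxt = r.asite_nt + 3
            ahead = ribs[i][pos + 1] if pos + 1 < len(ribs[i]) else None
            if ahead is not None and ahead.asite_nt - nxt < STERIC_NT:
                continue  # sterically blocked; no move
            if not past_cut(i, r.asite_nt) and nxt + 3 > limit(i):
                r.stalled = True  # ran into the cut: rescue substrate
                continue
            r.asite_nt = nxt
        elif u < r_init + r_elong + r_cleave:
            i, r = cleavable[int((u - r_init - r_elong) / config.k_cleave)]
            cut = (i, r.asite_nt + 2)  # RelE cuts after the A-site codon's 2nd nt
            if not past_cut(i, r.asite_nt) and (trunc is None or cut < trunc):
                trunc = cut
            r.stalled = True
            r.cleaved = True
        else:
            i, r = stalled[int((u - r_init - r_elong - r_cleave) / config.k_rescue)]
            ribs[i].remove(r)

    return [
        RibosomeSnapshot(
            gene_id=g.gene_id,
            ribosomes=ribs[i],
            truncation_nt=(trunc[1] if trunc is not None and trunc[0] == i else None),
        )
        for i, g in enumerate(genes_tu)
    ]
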