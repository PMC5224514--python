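"""End-to-end orchestration: simulate libraries, run every analysis stage
and emit a machine-readable summary.

The demo configuration simulates four footprint libraries from one
synthetic transcriptome — RelE digestion in vivo (full cleavage/rescue/
initiation dynamics), a wild-type MNase control, RelE and MNase digestions
in vitro (frozen ribosomes) — plus uniform RNA-seq, then runs the density,
metagene, operon, reading-frame and specificity stages on the SAM output
exactly as they would run on real alignments.  All randomness flows from
one seed; rerunning an identical configuration yields a byte-identical
summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import density as dens
from . import frames, io, operons, specificity
from .digest import digest, emit_reads, simulate_rnaseq, write_truth_table
from .dynamics import RiboSimConfig, SimMode, place_ribosomes, simulate_dynamics
from .nucleases import MNaseModel, RelEModel
from .transcriptome import FrameshiftSpec, generate_transcriptome

log = logging.getLogger(__name__)

_KNOWN_KEYS = None  # populated below


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the analysis conventions
    (0.1 reads/codon coverage floor, 5-fold operon uniformity, 1 rpkm
    expression floor, 30 nt ORF-end exclusion, 1000 nt metagene floor,
    MNase/RelE boundary offsets 12/1 nt, cloning windows 20-40 and 10-40
    nt)."""

    rng_seed: int = 0
    simulate: bool = True
    # --- simulation ---
    n_genes: int = 24
    n_operons: int | None = 5
    gene_length_range: tuple[int, int] = (350, 450)
    frameshift_enabled: bool = True
    frameshift_codon: int = 28
    frameshift_direction: int = 1
    n_footprints_per_gene: int = 400
    f_initiation: float = 0.2
    f_termination: float = 0.1
    invivo: dict = field(
        default_factory=lambda: {
            "k_init": 0.2,
            "k_elong": 10.0,
            "k_cleave": 0.3,
            "k_rescue": 0.5,
            "n_mrna_copies": 30,
            "sim_time": 120.0,
        }
    )
    invivo_depth: int = 20000
    rnaseq_reads: int = 50000
    # --- analysis inputs (used when simulate is false) ---
    genome: str | None = None
    annotation: str | None = None
    operon_table: str | None = None
    libraries: list = field(default_factory=list)  # {label, sam, nuclease}
    # --- thresholds ---
    min_reads_per_codon: float = 0.1
    operon_max_fold: float = 5.0
    min_rpkm: float = 1.0
    exclude_end_nt: int = 30
    min_metagene_len: int = 1000
    delta_mnase: int = 12
    delta_rele: int = 1
    p_nnc: float = 1.0
    window_invivo: tuple[int, int] = (20, 40)
    window_invitro: tuple[int, int] = (10, 40)
    rnaseq_window: tuple[int, int] = (40, 60)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gene_length_range", "window_invivo", "window_invitro", "rnaseq_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            if not self.libraries:
                raise ValueError("no libraries configured and simulation disabled")
            for lib in self.libraries:
                if not {"label", "sam", "nuclease"} <= set(lib):
                    raise ValueError("each library needs label, sam and nuclease")
            if self.genome is None or self.annotation is None:
                raise ValueError("genome and annotation paths required")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write TSV/JSON artifacts under ``outdir``.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline parameters: %s", dataclasses.asdict(config))

    rng = np.random.default_rng(config.rng_seed)

    if config.simulate:
        fs = (
            FrameshiftSpec(
                codon_index=config.frameshift_codon,
                direction=config.frameshift_direction,
            )
            if config.frameshift_enabled
            else None
        )
        tx = generate_transcriptome(
            n_genes=config.n_genes,
            n_operons=config.n_operons,
            gene_length_range=config.gene_length_range,
            frameshift_spec=fs,
            rng_seed=int(rng.integers(2**31)),
        )
        tx.write_fasta(out / "genome.fasta")
        tx.write_gff3(out / "annotation.gff3")
        tx.write_operon_tsv(out / "operons.tsv")
        rele = RelEModel(delta_rele=config.delta_rele, p_nnc=config.p_nnc)
        mnase = MNaseModel(delta_mnase=config.delta_mnase)

        # in vitro: frozen occupancy, digested twice (RelE+MNase / MNase alone)
        placement = place_ribosomes(
            tx,
            n_per_gene=config.n_footprints_per_gene,
            f_initiation=config.f_initiation,
            f_termination=config.f_termination,
            rng=int(rng.integers(2**31)),
        )
        vitro_cfg = RiboSimConfig(
            mode=SimMode.IN_VITRO, rng_seed=int(rng.integers(2**31))
        )
        snap_vitro = simulate_dynamics(tx, vitro_cfg, initial=placement)
        fp_rele_vitro = digest(snap_vitro, tx, rele=rele, mnase=mnase, rng=int(rng.integers(2**31)))
        fp_mnase_vitro = digest(snap_vitro, tx, rele=None, mnase=mnase, rng=int(rng.integers(2**31)))

        # in vivo: cleavage/rescue/initiation dynamics vs no-cleavage control
        vivo_cfg = RiboSimConfig(
            mode=SimMode.IN_VIVO,
            age_mixture=True,
            rng_seed=int(rng.integers(2**31)),
            **config.invivo,
        )
        snap_vivo = simulate_dynamics(tx, vivo_cfg)
        fp_rele_vivo = digest(
            snap_vivo, tx, rele=rele, mnase=mnase,
            rng=int(rng.integers(2**31)), n_reads=config.invivo_depth,
        )
        # wild-type control: no cleavage, observed past one traversal time
        # (the no-cleavage steady state), resampled to the same depth
        wt_cfg = dataclasses.replace(
            vivo_cfg,
            k_cleave=0.0,
            n_mrna_copies=6,
            sim_time=60.0,
            age_mixture=False,
            rng_seed=int(rng.integers(2**31)),
        )
        snap_wt = simulate_dynamics(tx, wt_cfg)
        fp_wt_vivo = digest(
            snap_wt, tx, rele=None, mnase=mnase,
            rng=int(rng.integers(2**31)), n_reads=config.invivo_depth,
        )

        fp_rnaseq = simulate_rnaseq(
            tx,
            fragment_window=config.rnaseq_window,
            n_reads=config.rnaseq_reads,
            rng_seed=int(rng.integers(2**31)),
        )
        lib_specs = [
            ("rele_invitro", fp_rele_vitro, "RELE", config.window_invitro),
            ("mnase_invitro", fp_mnase_vitro, "MNASE", config.window_invitro),
            ("rele_invivo", fp_rele_vivo, "RELE", config.window_invivo),
            ("wt_invivo", fp_wt_vivo, "MNASE", config.window_invivo),
            ("rnaseq", fp_rnaseq, "RNASEQ", config.rnaseq_window),
        ]
        libraries = []
        for label, fps, ntype, window in lib_specs:
            sam = out / f"{label}.sam"
            n = emit_reads(fps, window, sam, tx.genome)
            write_truth_table(fps, out / f"{label}.truth.tsv")
            log.info("%s: %d/%d footprints emitted", label, n, len(fps))
            libraries.append({"label": label, "sam": str(sam), "nuclease": ntype})
        genome = {k: v for k, v in tx.genome.items()}
        annotation = io.load_annotation(out / "annotation.gff3", out / "operons.tsv")
    else:
        genome = io.load_genome(config.genome)
        annotation = io.load_annotation(config.annotation, config.operon_table)
        libraries = config.libraries

    # --- density stage ---
    tracks: dict[str, dens.DensityTrack] = {}
    lib_nuclease: dict[str, str] = {}
    for lib in libraries:
        reads = io.load_alignments(lib["sam"], genome=genome)
        track = dens.assign_3prime_density(reads, genome, label=lib["label"])
        tracks[lib["label"]] = track
        lib_nuclease[lib["label"]] = lib["nuclease"]
        io.write_bedgraph(track.counts, out / f"{lib['label']}.3p")
        stats = dens.gene_stats(track, annotation, config.min_reads_per_codon)
        stats.to_csv(out / f"{lib['label']}.gene_stats.tsv", sep="\t", index=False)

    summary: dict = {"seed": config.rng_seed, "libraries": sorted(tracks)}

    # --- metagene stage ---
    summary["start_peaks"] = {}
    summary["stop_peaks"] = {}
    for label, track in tracks.items():
        if lib_nuclease[label] == "RNASEQ":
            continue
        prof = dens.metagene(
            track, annotation, "START", (-30, 45), config.min_metagene_len
        )
        prof.to_frame().to_csv(out / f"{label}.metagene_start.tsv", sep="\t", index=False)
        summary["start_peaks"][label] = dens.peak_offset(prof, (0, 30))
        try:
            prof_stop = dens.metagene(
                track, annotation, "STOP", (-30, 45), config.min_metagene_len
            )
        except ValueError:
            # e.g. an in vivo cleavage library with no density near stops
            summary["stop_peaks"][label] = None
            continue
        prof_stop.to_frame().to_csv(out / f"{label}.metagene_stop.tsv", sep="\t", index=False)
        summary["stop_peaks"][label] = dens.peak_offset(prof_stop, (0, 30))
        if config.make_plots:
            _plot_metagene(prof, out / f"{label}.metagene_start.png")

    # --- polarity + operon stage ---
    if "rele_invivo" in tracks and "wt_invivo" in tracks:

        def _covered(track):
            st = dens.gene_stats(track, annotation, config.min_reads_per_codon)
            keep = set(st.loc[st["kept"], "gene_id"])
            return io.AnnotationSet(
                genes=[g for g in annotation if g.gene_id in keep]
            )

        def _finite(d):
            return {
                k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in d.items()
            }

        _, pol = dens.polarity_ratio(tracks["rele_invivo"], _covered(tracks["rele_invivo"]))
        _, pol_wt = dens.polarity_ratio(tracks["wt_invivo"], _covered(tracks["wt_invivo"]))
        summary["polarity"] = {"rele_invivo": _finite(pol), "wt_invivo": _finite(pol_wt)}
        if "rnaseq" in tracks:
            # expression floors judged on the control library so that genes
            # fully depleted by cleavage still enter the comparison
            tu = operons.define_single_TUs(
                annotation,
                tracks["rnaseq"],
                tracks["wt_invivo"],
                max_fold=config.operon_max_fold,
                min_rpkm=config.min_rpkm,
            )
            ratios = operons.position_ratios(
                tracks["rele_invivo"], tracks["wt_invivo"], tu, annotation
            )
            ratios.to_csv(out / "operon_ratios.tsv", sep="\t", index=False)
            first = ratios.loc[ratios["bin"] == 1, "ratio"]
            deep = ratios.loc[ratios["bin"] >= 5, "ratio"]
            op_summary = {
                "n_genes": len(ratios),
                "bin_medians": {
                    str(b): float(g["ratio"].median()) for b, g in ratios.groupby("bin")
                },
            }
            if len(first) and len(deep):
                u, p = operons.rank_sum_test(first, deep)
                op_summary["rank_sum"] = {"U": u, "p": p}
            summary["operon"] = op_summary

    # --- reading-frame stage ---
    frame_lib = next(
        (lbl for lbl in ("rele_invitro", "rele_invivo") if lbl in tracks),
        None,
    )
    if frame_lib is None:
        frame_lib = next(
            (lbl for lbl, nt in lib_nuclease.items() if nt == "RELE"), None
        )
    if frame_lib is not None:
        track = tracks[frame_lib]
        before = frames.subcodon_fractions(track, annotation, config.exclude_end_nt)
        shifted = frames.nnc_shift(track, annotation, genome)
        after = frames.subcodon_fractions(shifted, annotation, config.exclude_end_nt)
        summary["frame_fractions"] = {
            "library": frame_lib,
            "before_shift": before.as_tuple(),
            "after_shift": after.as_tuple(),
        }
        heat = frames.codon_heatmap(track, annotation, genome)
        heat.fractions.to_csv(out / "codon_heatmap.tsv", sep="\t")
        summary["heatmap_ambiguous_fraction"] = heat.ambiguous_fraction
        calls = []
        for gene in annotation:
            call = frames.frameshift_scan(shifted, gene, genome)
            if call is not None:
                calls.append(dataclasses.asdict(call))
        with open(out / "frameshift_calls.tsv", "w") as fh:
            fh.write("gene_id\tcodon_index\tdirection\tscore\n")
            for c in calls:
                fh.write(
                    f"{c['gene_id']}\t{c['codon_index']}\t{c['direction']}\t{c['score']:.2f}\n"
                )
        summary["frameshift_calls"] = [
            {k: c[k] for k in ("gene_id", "codon_index", "direction")} for c in calls
        ]

    # --- specificity stage ---
    summary["end_bias"] = {}
    for lib in libraries:
        label = lib["label"]
        reads = io.load_alignments(lib["sam"], genome=genome)
        bias = specificity.end_bias(reads, genome, annotation, background="coverage")
        bias.enrichment.to_csv(out / f"{label}.end_bias.tsv", sep="\t")
        summary["end_bias"][label] = {
            "minus1": {b: round(float(bias.enrichment.loc[-1, b]), 4) for b in "ACGT"},
            "plus1": {b: round(float(bias.enrichment.loc[1, b]), 4) for b in "ACGT"},
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _plot_metagene(profile, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.offsets, profile.mean_density, lw=1)
    ax.set_xlabel(f"offset from {profile.anchor.lower()} codon (nt)")
    ax.set_ylabel("mean density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
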