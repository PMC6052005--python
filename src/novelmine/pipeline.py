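"""End-to-end orchestration of the unmapped-read mining pipeline.

Stages (in order): simulate -> triage -> assemble -> qc -> screen -> place
-> gaps.  Every stage reads and writes plain files with documented schemas
inside one working directory, so the orchestrator holds no hidden state,
any stage can be re-run or resumed, and every number in the final summary
is re-derivable from the stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from . import assembler, gaps as gaps_mod, io, mapper, novelty, placement, preprocess, qc, simulate

log = logging.getLogger("novelmine")

STAGES = ("simulate", "triage", "assemble", "qc", "screen", "place", "gaps")

SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineParams:
    """Tunable parameters of the analysis stages."""

    insert_mean: int = 290
    insert_tolerance: float = 0.5
    read_min_identity: float = 0.9
    include_discordant: bool = True
    trim_window: int = 4
    trim_min_mean_phred: float = 20.0
    trim_end_clip_max_phred: int = 3
    trim_min_length: int = 50
    primary_min_overlap: int = 40
    secondary_min_overlap: int = 100
    assembly_min_identity: float = 0.97
    secondary_min_length: int = 0
    min_mapq: int = 30
    cluster_radius: int | None = None  # default 2 * insert_mean
    min_support: int = 2
    qc_windowed: bool = False
    qc_drop_low_complexity: bool = False
    use_two_locus_placements: bool = False

    def trim_policy(self) -> preprocess.TrimPolicy:
        return preprocess.TrimPolicy(
            window=self.trim_window,
            window_min_mean_phred=self.trim_min_mean_phred,
            end_clip_max_phred=self.trim_end_clip_max_phred,
            min_length=self.trim_min_length,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def load_manifest(outdir: str) -> dict:
    with open(os.path.join(outdir, "sim", "manifest.json")) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: simulate.SimulationConfig, outdir: str) -> dict:
    io.ensure_dir(outdir)
    manifest = simulate.simulate_dataset(config, os.path.join(outdir, "sim"))
    log.info("simulate: %d samples, %d gaps", len(manifest["samples"]), config.n_gaps)
    return manifest


def run_triage(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    """Trim, map to the reference, and triage every sample's pairs."""
    tdir = io.ensure_dir(os.path.join(outdir, "triage"))
    reference = io.read_fasta(manifest["reference"])
    index = mapper.KmerIndex(reference)
    policy = params.trim_policy()
    all_counts = {}
    for sample in manifest["samples"]:
        sid = sample["sample_id"]
        trimmed: list[tuple] = []
        to_map: list[tuple[str, str]] = []
        for r1, r2 in io.read_fastq_pairs(sample["fastq1"], sample["fastq2"]):
            t1 = preprocess.trim_read(r1, policy)
            t2 = preprocess.trim_read(r2, policy)
            trimmed.append((r1.name, t1, t2))
            if t1 is not None and t2 is not None:
                to_map.append((r1.name + "/1", t1.sequence))
                to_map.append((r2.name + "/2", t2.sequence))
        alns = mapper.map_reads(to_map, index, min_identity=params.read_min_identity)
        rows = []
        for name, t1, t2 in trimmed:
            a1 = alns.get(name + "/1") if t1 is not None else None
            a2 = alns.get(name + "/2") if t2 is not None else None
            rows.append((t1, t2, a1, a2))
        result = preprocess.extract_unaligned_pool(
            rows,
            params.insert_mean,
            params.insert_tolerance,
            include_discordant=params.include_discordant,
        )
        io.write_fastq_pairs(
            os.path.join(tdir, f"{sid}_pool_1.fastq"),
            os.path.join(tdir, f"{sid}_pool_2.fastq"),
            result.pool,
        )
        io.write_pair_sam(
            os.path.join(tdir, f"{sid}_oea.sam"),
            {name: len(seq) for name, seq in reference.items()},
            [(pid, r1, r2, a1, a2) for pid, r1, r2, a1, a2 in result.oea],
        )
        all_counts[sid] = result.counts
        log.info("triage %s: %s", sid, result.counts)
    pd.DataFrame(all_counts).T.rename_axis("sample").to_csv(
        os.path.join(tdir, "class_counts.tsv"), sep="\t"
    )
    return all_counts


def run_assemble(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    """Primary per-sample assembly, then pooled secondary with debris binning."""
    tdir = os.path.join(outdir, "triage")
    adir = io.ensure_dir(os.path.join(outdir, "assembly"))
    all_primary: list[assembler.Contig] = []
    stats_rows = []
    for sample in manifest["samples"]:
        sid = sample["sample_id"]
        inputs = []
        pool1 = os.path.join(tdir, f"{sid}_pool_1.fastq")
        pool2 = os.path.join(tdir, f"{sid}_pool_2.fastq")
        if os.path.exists(pool1):
            for r1, r2 in io.read_fastq_pairs(pool1, pool2):
                inputs.append((r1.name + "/1", r1.sequence, r1.quality, sid))
                inputs.append((r2.name + "/2", r2.sequence, r2.quality, sid))
        contigs = assembler.assemble_greedy(
            inputs,
            min_overlap=params.primary_min_overlap,
            min_identity=params.assembly_min_identity,
            id_prefix=f"{sid}_c",
        )
        write_contig_fasta(os.path.join(adir, f"{sid}_primary.fa"), contigs)
        st = assembler.compute_stats(contigs)
        stats_rows.append({"set": f"{sid}_primary", **dataclasses.asdict(st)})
        all_primary += contigs
        log.info("assemble %s: %d reads -> %d primary contigs", sid, len(inputs), len(contigs))
    secondary, debris = assembler.secondary_assembly(
        all_primary,
        min_overlap=params.secondary_min_overlap,
        min_identity=params.assembly_min_identity,
        min_length=params.secondary_min_length,
    )
    write_contig_fasta(os.path.join(adir, "secondary.fa"), secondary)
    write_contig_fasta(os.path.join(adir, "debris.fa"), debris)
    st = assembler.compute_stats(secondary)
    stats_rows.append({"set": "secondary", **dataclasses.asdict(st)})
    pd.DataFrame(stats_rows).to_csv(os.path.join(adir, "stats.tsv"), sep="\t", index=False)
    log.info(
        "assemble: %d primary -> %d secondary contigs (%d debris)",
        len(all_primary),
        len(secondary),
        len(debris),
    )
    return {"n_primary": len(all_primary), "n_secondary": len(secondary), "n_debris": len(debris)}


def run_qc(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    adir = os.path.join(outdir, "assembly")
    qdir = io.ensure_dir(os.path.join(outdir, "qc"))
    contigs = read_contig_fasta(os.path.join(adir, "secondary.fa"))
    kept, rows = qc.run_qc(
        contigs,
        windowed=params.qc_windowed,
        drop_low_complexity=params.qc_drop_low_complexity,
    )
    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
        os.path.join(qdir, "qc.tsv"), sep="\t", index=False
    )
    write_contig_fasta(os.path.join(qdir, "filtered.fa"), kept)
    gc_vals = [r.gc_percent for r in rows if r.gc_percent is not None]
    out = {
        "n_in": len(contigs),
        "n_kept": len(kept),
        "n_duplicates": sum(1 for r in rows if r.duplicate_of),
        "n_low_complexity": sum(1 for r in rows if r.low_complexity),
        "mean_gc": float(np.mean(gc_vals)) if gc_vals else None,
    }
    log.info("qc: %s", out)
    return out


def run_screen(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    qdir = os.path.join(outdir, "qc")
    sdir = io.ensure_dir(os.path.join(outdir, "screen"))
    contigs = read_contig_fasta(os.path.join(qdir, "filtered.fa"))
    reference = io.read_fasta(manifest["reference"])
    verdicts = novelty.screen_against_reference(contigs, reference)
    novel = novelty.filter_novel(contigs, verdicts)
    pd.DataFrame([dataclasses.asdict(v) for v in verdicts]).to_csv(
        os.path.join(sdir, "novelty.tsv"), sep="\t", index=False
    )
    write_contig_fasta(os.path.join(sdir, "novel.fa"), novel)
    counts = {"n_in": len(contigs), "n_novel": len(novel)}
    for v in verdicts:
        counts[v.status.lower()] = counts.get(v.status.lower(), 0) + 1
    log.info("screen: %s", counts)
    return counts


def run_place(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    """Map OEA mates onto the novel contigs, harvest anchors, cluster, verify."""
    tdir = os.path.join(outdir, "triage")
    sdir = os.path.join(outdir, "screen")
    pdir = io.ensure_dir(os.path.join(outdir, "placement"))
    contigs = read_contig_fasta(os.path.join(sdir, "novel.fa"))
    contig_seqs = {c.contig_id: c.sequence for c in contigs}
    contig_lengths = {c.contig_id: len(c.sequence) for c in contigs}
    reference = io.read_fasta(manifest["reference"])

    oea_rows = []
    to_map: list[tuple[str, str]] = []
    for sample in manifest["samples"]:
        sam = os.path.join(tdir, f"{sample['sample_id']}_oea.sam")
        if not os.path.exists(sam):
            continue
        for pid, r1, r2, a1, a2 in io.read_pair_sam(sam):
            oea_rows.append((pid, r1, r2, a1, a2))
            unmapped = r2 if a1 is not None else r1
            slot = "/2" if a1 is not None else "/1"
            if unmapped is not None:
                to_map.append((pid + slot, unmapped.sequence))
    anchors: list[placement.OeaAnchor] = []
    counts: dict = {"pairs": len(oea_rows), "anchors": 0}
    if contig_seqs and to_map:
        cindex = mapper.KmerIndex(contig_seqs)
        calns = mapper.map_reads(to_map, cindex, min_identity=params.read_min_identity)
        evidence = []
        for pid, r1, r2, a1, a2 in oea_rows:
            c1 = calns.get(pid + "/1") if a1 is None else None
            c2 = calns.get(pid + "/2") if a2 is None else None
            evidence.append((pid, a1, a2, c1, c2))
        anchors, counts = placement.harvest_anchors(
            evidence, contig_lengths, params.insert_mean, min_mapq=params.min_mapq
        )
    placements = placement.place_contigs(
        anchors,
        contig_lengths,
        params.insert_mean,
        cluster_radius=params.cluster_radius,
        min_support=params.min_support,
    )
    placements = placement.verify_placements(
        placements,
        contig_seqs,
        reference,
        pad=2 * params.insert_mean,
        verify_two=params.use_two_locus_placements,
    )
    io.write_bed(os.path.join(pdir, "placements.bed"), placement.placements_to_bed(placements))
    summary = placement.classification_summary(placements)
    summary["anchor_counts"] = counts
    rows = [
        {
            "contig_id": cid,
            "length": p.contig_length,
            "classification": p.classification,
            "n_anchors": p.n_anchors,
            "n_loci": len(p.loci),
            "verified": any(l.verified for l in p.loci),
        }
        for cid, p in sorted(placements.items())
    ]
    pd.DataFrame(rows).to_csv(os.path.join(pdir, "classification.tsv"), sep="\t", index=False)
    log.info("place: %s", summary)
    return summary


def run_gaps(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    pdir = os.path.join(outdir, "placement")
    gdir = io.ensure_dir(os.path.join(outdir, "gaps"))
    bed = io.read_bed(os.path.join(pdir, "placements.bed"))
    wanted = {"SINGLE"} | ({"TWO"} if params.use_two_locus_placements else set())
    placements = [
        (r[0], r[1], r[2], str(r[3]))
        for r in bed
        if len(r) >= 8 and str(r[6]) in wanted and str(r[7]) == "1"
    ]
    gap_list = gaps_mod.gaps_from_bed(io.read_bed(manifest["gaps"]))
    features = io.read_gff3(manifest["genes_gff3"]) if manifest.get("genes_gff3") else []
    bacs = io.read_bed(manifest["bacs"]) if manifest.get("bacs") else None
    report = gaps_mod.build_report(placements, gap_list, features, bacs)
    rows = []
    for r in report.rows:
        d = dataclasses.asdict(r)
        d["contig_ids"] = ",".join(r.contig_ids)
        d["genic_classes"] = ",".join(r.genic_classes)
        d["gene_ids"] = ",".join(r.gene_ids)
        rows.append(d)
    pd.DataFrame(rows).to_csv(os.path.join(gdir, "gap_report.tsv"), sep="\t", index=False)
    aggregates = {
        k: v
        for k, v in dataclasses.asdict(report).items()
        if k not in ("rows",)
    }
    io.write_json(os.path.join(gdir, "gap_summary.json"), aggregates)
    log.info("gaps: %d gap contigs, %d closed", report.n_gap_contigs, report.n_gaps_closed)
    return aggregates


# ---------------------------------------------------------------------------
# contig FASTA round-trip with provenance


def write_contig_fasta(path: str, contigs: Sequence[assembler.Contig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            desc = f"n_reads={c.n_reads} samples={','.join(sorted(c.sample_ids))} tier={c.tier}"
            fh.write(f">{c.contig_id} {desc}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")


def read_contig_fasta(path: str) -> list[assembler.Contig]:
    seqs = io.read_fasta(path)
    descs = io.read_fasta_descriptions(path)
    out = []
    for name, seq in seqs.items():
        fields = dict(
            kv.split("=", 1) for kv in descs.get(name, "").split() if "=" in kv
        )
        out.append(
            assembler.Contig(
                contig_id=name,
                sequence=seq,
                n_reads=int(fields.get("n_reads", 1)),
                sample_ids=frozenset(filter(None, fields.get("samples", "").split(","))),
                tier=fields.get("tier", "secondary"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# truth evaluation


def evaluate_against_truth(manifest: dict, params: PipelineParams, outdir: str) -> dict:
    """Score the pipeline's output against the simulation truth table."""
    truth = simulate.load_truth(manifest["truth"])
    gdir = os.path.join(outdir, "gaps")
    pdir = os.path.join(outdir, "placement")
    with open(os.path.join(gdir, "gap_summary.json")) as fh:
        gap_summary = json.load(fh)
    report = pd.read_csv(os.path.join(gdir, "gap_report.tsv"), sep="\t")
    bed = io.read_bed(os.path.join(pdir, "placements.bed"))

    fills = [t for t in truth if t.kind == "gap_fill"]
    closed = 0
    for t in fills:
        row = report[
            (report["target"] == t.chrom)
            & (report["start"] == t.ref_start)
            & (report["end"] == t.ref_end)
        ]
        if len(row) and bool(row.iloc[0]["closed"]):
            closed += 1

    insertions = [t for t in truth if t.kind == "nongap_insertion"]
    single_verified = [
        r for r in bed if len(r) >= 8 and str(r[6]) == "SINGLE" and str(r[7]) == "1"
    ]
    placed_ok = 0
    for t in insertions:
        hit = False
        for r in single_verified:
            mid = (int(r[1]) + int(r[2])) / 2
            if r[0] == t.chrom and abs(mid - t.ref_start) <= params.insert_mean:
                hit = True
                break
        placed_ok += int(hit)

    # confident placements far from every truth locus
    truth_loci = [(t.chrom, t.ref_start, max(t.ref_end, t.ref_start + 1)) for t in truth]
    far = 0
    for r in single_verified:
        dists = []
        for chrom, s, e in truth_loci:
            if r[0] != chrom:
                continue
            d = max(s - int(r[2]), int(r[1]) - e, 0)
            dists.append(d)
        if not dists or min(dists) > 10 * params.insert_mean:
            far += 1

    out = {
        "n_gap_fills": len(fills),
        "n_gap_fills_closed": closed,
        "gap_fill_closure_rate": closed / len(fills) if fills else None,
        "n_nongap_insertions": len(insertions),
        "n_nongap_single_placed": placed_ok,
        "nongap_single_placement_rate": placed_ok / len(insertions) if insertions else None,
        "n_confident_far_placements": far,
        "n_gaps_closed_total": gap_summary["n_gaps_closed"],
    }
    log.info("truth_eval: %s", out)
    return out


# ---------------------------------------------------------------------------
# run-all


def run_all(
    config: simulate.SimulationConfig,
    outdir: str,
    params: PipelineParams | None = None,
    from_stage: str = "simulate",
) -> dict:
    """Run all stages in order; resume from ``from_stage`` if its inputs exist."""
    params = params or PipelineParams()
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; expected one of {STAGES}")
    start = STAGES.index(from_stage)
    io.ensure_dir(outdir)
    summary: dict = {"schema_version": SCHEMA_VERSION, "stages": {}}
    if start == 0:
        manifest = run_simulate(config, outdir)
    else:
        manifest = load_manifest(outdir)
    runners = {
        "triage": run_triage,
        "assemble": run_assemble,
        "qc": run_qc,
        "screen": run_screen,
        "place": run_place,
        "gaps": run_gaps,
    }
    for stage in STAGES[max(start, 1) :]:
        summary["stages"][stage] = runners[stage](manifest, params, outdir)
    if os.path.exists(manifest.get("truth", "")):
        summary["truth_eval"] = evaluate_against_truth(manifest, params, outdir)
    n_novel = summary["stages"].get("screen", {}).get("n_novel")
    if n_novel == 0:
        summary["message"] = "no novel sequence detected"
    io.write_json(os.path.join(outdir, "summary.json"), summary)
    return summary
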