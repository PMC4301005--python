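"""End-to-end finishing workflow: mask rRNA contigs, annotate ends, handle
N-stretches, place small contigs, scaffold, plan gap closure, detect
rearrangements, and validate — with every stage's artifacts written to disk
and a machine-readable report last.

Wet-lab steps are replaced by their in-silico analogs: gap amplicons are
predicted by in-silico PCR against a supplied template genome (a finished
relative or a simulated source); Sanger reads are modeled by the 750/1000 bp
read-span model. Without a reference the scaffold and rearrangement stages
are skipped; without a PCR template gaps stay classified "unknown" and get
traditional walking plans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from . import __version__
from .ambiguity import (
    NStretch,
    design_n_flanking_primers,
    find_n_stretches,
    place_small_contigs,
)
from .gap_planner import (
    GapPrimerPair,
    classify_gap_rdna,
    design_gap_primers,
    plan_rdna_walk,
    plan_traditional_walk,
)
from .primers import Undesignable, UniquenessScope, simulate_pcr
from .rdna import (
    ConsensusGene,
    annotate_contig_ends,
    cluster_operons,
    mask_rrna_contigs,
    scan_contigs,
)
from .rearrange import call_rearrangements, design_junction_primers, window_map
from .reports import write_bed, write_json, write_primer_tsv, write_tsv
from .scaffold import anchor_contigs, estimate_gap_sizes, order_and_orient, ReferenceIndex
from .seqio import Contig, write_fasta
from .stats import assembly_stats
from .validation import verify_draft_coverage


@dataclass
class FinishingConfig:
    """Every tunable the workflow uses; a flat key=value file maps onto the
    field names and CLI flags override it."""

    scan_min_identity: float = 90.0
    scan_min_fragment: int = 100
    mask_max_length: int = 2000
    mask_min_covered: float = 0.8
    end_window: int = 200
    operon_max_span: int = 10000
    n_stretch_min: int = 3
    small_contig_max: int = 1000
    flank_window: int = 300
    min_flank_identity: float = 0.95
    anchor_k: int = 21
    gap_offset_min: int = 250
    gap_offset_max: int = 350
    max_product: int = 15000
    rearrange_window: int = 10000
    rearrange_step: int = 5000
    min_jump: int = 50000
    validate_min_identity: float = 99.0
    validate_min_covered: float = 0.99
    design_flanking_primers: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "FinishingConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            else:
                setattr(cfg, key, type(current)(value))
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class FinishingReport:
    version: str
    config: dict
    stats: dict = field(default_factory=dict)
    masking: dict = field(default_factory=dict)
    end_annotation: dict = field(default_factory=dict)
    n_stretches: dict = field(default_factory=dict)
    placements: dict = field(default_factory=dict)
    scaffold: dict = field(default_factory=dict)
    gaps: list = field(default_factory=list)
    rearrangements: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    contig_trajectory: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)


def _out(outdir: str | Path | None, *parts: str) -> Path | None:
    if outdir is None:
        return None
    p = Path(outdir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def run_finishing_plan(
    contigs: list[Contig],
    reference: Contig | str | None = None,
    genes: list[ConsensusGene] | None = None,
    pcr_template: str | None = None,
    final_assembly: str | None = None,
    outdir: str | Path | None = None,
    config: FinishingConfig | None = None,
    log=lambda msg: None,
) -> FinishingReport:
    """Execute the finishing workflow in order; see the module docstring.

    ``pcr_template`` stands in for genomic DNA in the in-silico PCRs that
    produce gap amplicons; ``final_assembly`` triggers the closing
    draft-coverage validation.
    """
    cfg = config or FinishingConfig()
    report = FinishingReport(version=__version__, config=cfg.to_dict())
    ref_seq = reference.seq if isinstance(reference, Contig) else reference
    trajectory = [("input", len(contigs))]

    # --- stage 0: input statistics -----------------------------------------
    log("stats: computing assembly statistics")
    st = assembly_stats(contigs)
    report.stats = {"contig_count": st.contig_count, "total_bases": st.total_bases, "n50": st.n50}

    # --- stage 1: rRNA masking ---------------------------------------------
    working = list(contigs)
    hits = []
    if genes:
        log("mask-rdna: scanning contigs for rDNA fragments")
        hits = scan_contigs(working, genes, cfg.scan_min_identity, cfg.scan_min_fragment)
        classes, working = mask_rrna_contigs(
            working, hits, cfg.mask_max_length, cfg.mask_min_covered
        )
        masked = [c for c in classes if c.masked]
        report.masking = {
            "masked_count": len(masked),
            "masked": [{"contig": c.contig_id, "length": c.length,
                        "rdna_fraction": c.rdna_fraction, "genes": c.genes} for c in masked],
            "remaining": len(working),
        }
        if outdir:
            write_tsv(_out(outdir, "mask", "masking_report.tsv"),
                      [{"contig": c.contig_id, "length": c.length, "masked": c.masked,
                        "rdna_fraction": c.rdna_fraction,
                        "genes": ",".join(c.genes)} for c in classes])
            write_json(_out(outdir, "mask", "masking_report.json"), report.masking)
            write_bed(_out(outdir, "mask", "rdna_hits.bed"),
                      [(h.contig_id, h.start, h.end, h.gene, int(h.identity * 10), h.strand)
                       for h in hits])
        trajectory.append(("after_masking", len(working)))

        # --- stage 2: end annotation ---------------------------------------
        log("mask-rdna: annotating contig ends")
        kept_ids = {c.id for c in working}
        kept_hits = [h for h in hits if h.contig_id in kept_ids]
        _classes, tally = annotate_contig_ends(working, kept_hits, cfg.end_window)
        report.end_annotation = tally
    else:
        report.stages_skipped += ["mask-rdna", "end-annotation"]

    # --- stage 3: N-stretches and flanking primers -------------------------
    log("find-n: locating ambiguous-base stretches")
    scope = UniquenessScope(contigs)
    stretches = [s for c in working for s in find_n_stretches(c, cfg.n_stretch_min)]
    flanking: list[dict] = []
    if cfg.design_flanking_primers:
        by_id = {c.id: c for c in working}
        for stx in stretches:
            res = design_n_flanking_primers(by_id[stx.contig_id], stx, scope=scope)
            if isinstance(res, Undesignable):
                flanking.append({"contig": stx.contig_id, "start": stx.start,
                                 "end": stx.end, "status": "undesignable",
                                 "reason": res.reason})
            else:
                flanking.append({"contig": stx.contig_id, "start": stx.start,
                                 "end": stx.end, "status": "ok",
                                 "forward": res.forward.seq, "reverse": res.reverse.seq})
    report.n_stretches = {
        "count": len(stretches),
        "min_length": min((s.length for s in stretches), default=0),
        "max_length": max((s.length for s in stretches), default=0),
        "primer_pairs_designed": sum(1 for f in flanking if f["status"] == "ok"),
        "undesignable": sum(1 for f in flanking if f["status"] == "undesignable"),
    }
    if outdir:
        write_bed(_out(outdir, "nstretch", "n_stretches.bed"),
                  [(s.contig_id, s.start, s.end, f"N{s.length}", 0, "+") for s in stretches])
        if flanking:
            write_tsv(_out(outdir, "nstretch", "flanking_primers.tsv"), flanking)

    # --- stage 4: small-contig placement -----------------------------------
    log("place-small: fitting small contigs into N-stretches")
    smalls = [c for c in working if c.length < cfg.small_contig_max]
    hosts = [c for c in working if c.length >= cfg.small_contig_max]
    host_stretches = [s for s in stretches if s.contig_id in {h.id for h in hosts}]
    matches, unplaced, working = place_small_contigs(
        smalls, hosts, host_stretches, cfg.flank_window, cfg.min_flank_identity
    )
    # annotate which stretches were satisfied by a placement
    satisfied = {(m.host_id, m.stretch.start, m.stretch.end) for m in matches}
    for f in flanking:
        f["satisfied_by_placement"] = (f["contig"], f["start"], f["end"]) in satisfied
    report.placements = {
        "placed": len(matches),
        "unplaced": [{"contig": u.small_id, "reason": u.reason} for u in unplaced],
        "remaining": len(working),
        "detail": [{"small": m.small_id, "host": m.host_id, "stretch_start": m.stretch.start,
                    "orientation": m.orientation, "flank_identity": m.score} for m in matches],
    }
    if outdir:
        write_json(_out(outdir, "place", "placements.json"), report.placements)
        write_fasta(working, _out(outdir, "place", "merged_contigs.fasta"))
    trajectory.append(("after_placement", len(working)))

    # --- stage 5: scaffold --------------------------------------------------
    layout = None
    gap_records = []
    ref_index = None
    if ref_seq:
        log("scaffold: anchoring contigs to the reference")
        ref_index = ReferenceIndex(ref_seq, cfg.anchor_k)
        anchors = anchor_contigs(working, ref_seq, cfg.anchor_k, index=ref_index)
        layout = order_and_orient(working, anchors)
        gap_records = estimate_gap_sizes(layout, working, anchors) if len(layout.placed) > 1 else []
        report.scaffold = {
            "placed": [{"contig": p.contig_id, "orientation": p.orientation,
                        "ref_start": p.ref_start} for p in layout.placed],
            "unplaced": layout.unplaced,
            "gap_count": len(gap_records),
            "mean_gap": (sum(g.size for g in gap_records) / len(gap_records))
            if gap_records else None,
        }
        if outdir:
            write_tsv(_out(outdir, "scaffold", "layout.tsv"),
                      [{"contig": p.contig_id, "orientation": p.orientation,
                        "ref_start_estimate": p.ref_start,
                        "ref_start_1based": p.ref_start + 1} for p in layout.placed])
    else:
        report.stages_skipped += ["scaffold"]

    # --- stage 6: gap closure planning -------------------------------------
    gap_reports = []
    if layout is not None and gap_records:
        log("plan-gaps: designing gap primers and walk plans")
        by_id = {c.id: c for c in working}
        orient = {p.contig_id: p.orientation for p in layout.placed}
        for i, gap in enumerate(gap_records):
            gap_id = f"{gap.left_id}--{gap.right_id}"
            entry: dict = {"gap": gap_id, "estimated_size": gap.size}
            pair = design_gap_primers(
                gap_id, by_id[gap.left_id], orient[gap.left_id],
                by_id[gap.right_id], orient[gap.right_id],
                scope=scope, offset_range=(cfg.gap_offset_min, cfg.gap_offset_max),
            )
            if isinstance(pair, Undesignable):
                entry["primers"] = "undesignable"
                entry["reason"] = pair.reason
                entry["classification"] = "unknown"
                entry["plan"] = None
                gap_reports.append(entry)
                continue
            entry["forward"] = pair.forward.seq
            entry["reverse"] = pair.reverse.seq
            amp = None
            if pcr_template:
                prods = simulate_pcr(pcr_template, pair.forward, pair.reverse,
                                     max_product=cfg.max_product)
                amp = prods[0] if prods else None
            if amp is None:
                entry["classification"] = "unknown"
                plan = plan_traditional_walk(gap_id, max(1, abs(gap.size)))
            else:
                entry["amplicon_length"] = amp.length
                cls = classify_gap_rdna(gap_id, amp.seq, genes)
                entry["classification"] = {
                    "16S": cls.has_16s, "23S": cls.has_23s, "5S": cls.has_5s,
                    "product_16S": cls.product_16s, "product_23S": cls.product_23s,
                }
                gap.rdna = "present" if cls.rdna_present else "absent"
                if cls.has_16s and cls.has_23s and genes:
                    plan = plan_rdna_walk(gap_id, amp.seq, pair, genes)
                else:
                    plan = plan_traditional_walk(gap_id, max(1, abs(gap.size)))
            entry["plan"] = {
                "strategy": plan.strategy,
                "reactions": len(plan.reactions),
                "stage_equivalent": plan.stage_equivalent,
                "uncovered": plan.uncovered,
                "degraded": plan.degraded_segments,
            }
            gap_reports.append(entry)
            if outdir:
                write_json(_out(outdir, "gaps", f"{gap_id}.plan.json"), {
                    "gap": gap_id, "strategy": plan.strategy,
                    "stage_equivalent": plan.stage_equivalent,
                    "uncovered": plan.uncovered,
                    "reactions": [{
                        "id": r.reaction_id, "primer": r.primer.name,
                        "sequence": r.primer.seq, "direction": r.direction,
                        "read_start": r.read_start, "read_end": r.read_end,
                        "depends_on": r.depends_on} for r in plan.reactions],
                })
        report.gaps = gap_reports
        if outdir:
            write_tsv(_out(outdir, "gaps", "gap_table.tsv"),
                      [{"gap": e["gap"], "estimated_size": e["estimated_size"],
                        "classification": str(e.get("classification")),
                        "strategy": (e["plan"] or {}).get("strategy"),
                        "reactions": (e["plan"] or {}).get("reactions"),
                        "stages": (e["plan"] or {}).get("stage_equivalent")}
                       for e in gap_reports])
            from .primers import Primer

            primer_rows = []
            for e in gap_reports:
                if "forward" in e:
                    primer_rows.append((Primer(e["gap"] + "F", e["forward"]), "gap", "F"))
                    primer_rows.append((Primer(e["gap"] + "R", e["reverse"]), "gap", "R"))
            write_primer_tsv(_out(outdir, "gaps", "gap_primers.tsv"), primer_rows)
    else:
        report.stages_skipped += ["plan-gaps"]

    # --- stage 7: rearrangement screen -------------------------------------
    if layout is not None and ref_index is not None:
        log("rearrange: windowed draft-vs-reference placement")
        spacer = "N" * cfg.rearrange_window
        pieces = []
        scaffold_stretches: list[NStretch] = []
        offset_map = []
        pos = 0
        by_id = {c.id: c for c in working}
        from .iupac import revcomp as _rc

        for p in layout.placed:
            seq = by_id[p.contig_id].seq
            if p.orientation == "-":
                seq = _rc(seq)
            pieces.append(seq)
            offset_map.append((p.contig_id, pos, pos + len(seq)))
            for stx in find_n_stretches(Contig(p.contig_id, seq), cfg.n_stretch_min):
                scaffold_stretches.append(
                    NStretch(p.contig_id, pos + stx.start, pos + stx.end)
                )
            pieces.append(spacer)
            pos += len(seq) + len(spacer)
        pseudo = "".join(pieces)
        placements = window_map(pseudo, ref_index, cfg.rearrange_window, cfg.rearrange_step)
        calls = call_rearrangements(placements, cfg.min_jump, cfg.rearrange_step,
                                    scaffold_stretches)
        call_entries = []
        for call in calls:
            contig = next((cid for cid, s, e in offset_map
                           if s <= call.d_start < e), None)
            jx = design_junction_primers(call, pseudo, scope=scope)
            call_entries.append({
                "type": call.type, "contig": contig,
                "scaffold_start": call.d_start, "scaffold_end": call.d_end,
                "block_size": call.block_size,
                "ref_start": call.r_start, "ref_end": call.r_end,
                "junction_primers": [
                    {"junction": j.junction, "left": j.left.seq, "right": j.right.seq,
                     "product": j.product_length}
                    if not isinstance(j, Undesignable) else {"undesignable": j.reason}
                    for j in jx
                ],
            })
        report.rearrangements = {"calls": call_entries,
                                 "windows": len(placements),
                                 "unplaced_windows": sum(1 for p in placements if not p.placed)}
        if outdir:
            write_json(_out(outdir, "rearrange", "calls.json"), call_entries)
            write_tsv(_out(outdir, "rearrange", "window_placements.tsv"),
                      [{"window": p.window_id, "draft_start": p.d_start,
                        "draft_end": p.d_end, "ref_start": p.r_start,
                        "ref_end": p.r_end, "strand": p.strand,
                        "support": p.support} for p in placements])
    else:
        report.stages_skipped += ["rearrange"]

    # --- stage 8: validation -----------------------------------------------
    if final_assembly:
        log("validate: checking draft coverage in the final assembly")
        rep = verify_draft_coverage(
            contigs, final_assembly, cfg.validate_min_identity, cfg.validate_min_covered
        )
        report.validation = {
            "pass": rep.passed,
            "failing": rep.failing,
            "contigs": [{"contig": p.contig_id, "identity": p.identity,
                         "covered": p.covered_fraction, "note": p.note}
                        for p in rep.placements],
        }
        if outdir:
            write_json(_out(outdir, "validate", "coverage.json"), report.validation)
    else:
        report.stages_skipped += ["validate"]

    report.contig_trajectory = trajectory
    if outdir:
        write_json(_out(outdir, "report.json"), report)
    log("done")
    return report
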