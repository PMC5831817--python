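"""End-to-end orchestration of the similarity-map workflow.

Stages, mirroring the published workflow: build and calibrate the domain
profile from the seed alignment; scan candidates; collapse redundancy;
build a first all-against-all map and keep only clusters holding seed
sequences; re-inflate the kept clusters; drop multi-domain sequences
(mis-annotations / concatenations); run the final all-against-all; emit
maps at each analysis cutoff with a force-directed layout; and produce
the connectivity-based assignment report, optionally with the
neighbor-joining contrast.  Every stage logs its in/out counts and the
run manifest (config snapshot, seeds, artifact checksums) is written on
success and on failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import align, assign, njtree, profile as prof, seqio, simmap, simulate

logger = logging.getLogger("hoxmap")


@dataclass
class PipelineConfig:
    # input mode A: files
    candidate_fasta: str | None = None
    seed_alignment: str | None = None
    seed_id_file: str | None = None
    # input mode B: synthetic scenario
    synthetic_preset: str | None = None
    synthetic_severity: float = 1.0
    # parameters
    report_cutoff: float = 1e-2
    analysis_cutoffs: tuple[float, ...] = (1e-33, 1e-40)
    redundancy_threshold: float = 0.95
    calibration_fpr: float = 1e-3
    gap_open: int = 11
    gap_extend: int = 1
    tie_margin: float = 0.25
    layout_dims: int = 2
    layout_seed: int = 0
    rng_seed: int = 0
    run_nj_contrast: bool = True
    output_dir: str = "hoxmap_out"

    def validate(self) -> None:
        if any(c > self.report_cutoff for c in self.analysis_cutoffs):
            raise ValueError("analysis cutoffs must be <= report_cutoff")
        if not self.analysis_cutoffs:
            raise ValueError("need at least one analysis cutoff")
        file_mode = self.candidate_fasta is not None
        synth_mode = self.synthetic_preset is not None
        if file_mode == synth_mode:
            raise ValueError("exactly one of candidate_fasta / synthetic_preset required")
        if file_mode:
            for p in (self.candidate_fasta, self.seed_alignment):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or unresolvable: {p}")
            if self.seed_id_file is not None and not Path(self.seed_id_file).exists():
                raise ValueError(f"seed id file unresolvable: {self.seed_id_file}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None
    status: str = "running"
    failing_stage: str | None = None

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})
        logger.info("stage %s: %s", stage, counts)

    def write(self, outdir: Path) -> None:
        self.finished = time.time()
        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                self.checksums[p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )


@dataclass
class PipelineResult:
    report: assign.AssignmentReport
    graph: simmap.SimilarityGraph
    layout: simmap.LayoutState
    manifest: RunManifest
    nj_tree: njtree.InferredTree | None = None
    attraction: njtree.AttractionDetail | None = None


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow; artifacts land in ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds={"rng_seed": config.rng_seed, "layout_seed": config.layout_seed},
    )
    stage = "setup"
    try:
        # ---- stage 1: inputs ------------------------------------------------
        stage = "load"
        if config.synthetic_preset is not None:
            dataset = simulate.hox_parahox_scenario(
                config.synthetic_preset, config.synthetic_severity, config.rng_seed
            )
            seqs = dataset.sequences
            seed_rows = dataset.seed_alignment()
            seed_ids = set(dataset.seed_ids())
            simulate.write_design(dataset.truth, outdir / "design.cfg")
        else:
            dataset = None
            seqs = seqio.read_fasta(config.candidate_fasta)
            seed_rows = prof.read_seed_alignment(config.seed_alignment)
            if config.seed_id_file:
                seed_ids = {
                    l.strip() for l in Path(config.seed_id_file).read_text().splitlines() if l.strip()
                }
            else:
                seed_ids = {seqs[0].seq_id}
        seqio.write_fasta(seqs, outdir / "candidates.fasta")
        manifest.record(stage, n_sequences=len(seqs), n_seed_rows=len(seed_rows))

        # ---- stage 2: profile + scan ---------------------------------------
        stage = "profile"
        model = prof.build_profile(seed_rows)
        prof.calibrate_threshold(
            model, fpr=config.calibration_fpr, seed=config.rng_seed
        )
        model.write_tsv(outdir / "profile.tsv")
        all_hits = {s.seq_id: prof.scan_sequence(model, s) for s in seqs}
        prof.write_hit_table(
            [h for hits in all_hits.values() for h in hits], outdir / "domain_hits.tsv"
        )
        with_domain = [s for s in seqs if all_hits[s.seq_id]]
        manifest.record(
            stage,
            threshold=model.score_threshold,
            n_with_domain=len(with_domain),
            n_zero_hit=len(seqs) - len(with_domain),
        )

        # ---- stage 3: redundancy clustering --------------------------------
        stage = "cluster"
        rmap = seqio.cluster_redundant(with_domain, config.redundancy_threshold)
        rmap.write_tsv(outdir / "redundancy.tsv")
        reps = [s for s in with_domain if rmap.representative_of[s.seq_id] == s.seq_id]
        manifest.record(stage, n_in=len(with_domain), n_representatives=len(reps))

        # ---- stage 4: first map + seed-cluster selection -------------------
        stage = "first_map"
        scheme = align.ScoringScheme(
            gap_open=config.gap_open, gap_extend=config.gap_extend
        )
        first_hits = align.all_against_all(reps, scheme, config.report_cutoff)
        first_graph = simmap.SimilarityGraph(
            reps, align.build_edges(first_hits, config.report_cutoff), config.report_cutoff
        )
        comps = simmap.connected_components(first_graph)
        seed_reps = {rmap.representative_of[s] for s in seed_ids if s in rmap.representative_of}
        selected = simmap.select_seed_clusters(comps, seed_reps or set(list(first_graph.node_ids)[:1]))
        manifest.record(stage, n_components=len(comps), n_selected=len(selected))

        # ---- stage 5: re-inflation -----------------------------------------
        stage = "reinflate"
        inflated = seqio.reinflate(
            {r for r in selected if rmap.representative_of.get(r) == r},
            rmap,
            with_domain,
        )
        manifest.record(stage, n_out=len(inflated))

        # ---- stage 6: multi-domain filter ----------------------------------
        stage = "multidomain_filter"
        fres = prof.filter_multidomain(inflated, model)
        seqio.write_fasta(fres.kept, outdir / "final_set.fasta")
        seqio.write_annotation_table(fres.kept, outdir / "annotations.tsv")
        manifest.record(
            stage,
            n_kept=len(fres.kept),
            n_removed=len(fres.removed),
            n_zero_hit_flagged=len(fres.zero_hit_ids),
        )

        # ---- stage 7: final all-against-all + maps + layout ----------------
        stage = "align"
        hits = align.all_against_all(fres.kept, scheme, config.report_cutoff)
        align.write_hits_tsv(hits, outdir / "hits.tsv")
        base_graph = simmap.SimilarityGraph(
            fres.kept, align.build_edges(hits, config.report_cutoff), config.report_cutoff
        )
        manifest.record(stage, n_hits=len(hits), n_edges=len(base_graph.edges))

        stage = "layout"
        analysis_graphs = {
            c: simmap.apply_cutoff(base_graph, c) for c in config.analysis_cutoffs
        }
        layout_cutoff = max(config.analysis_cutoffs)  # the default-resolution map
        state = simmap.layout(
            analysis_graphs[layout_cutoff], dims=config.layout_dims, seed=config.layout_seed
        )
        for c, g in analysis_graphs.items():
            simmap.write_map(g, state, outdir / f"map_{c:.0e}.txt")
        simmap.save_scatter(analysis_graphs[layout_cutoff], state, outdir / "map.svg")
        manifest.record(
            stage,
            converged=state.converged,
            iterations=state.iterations_run,
            edges_per_cutoff={f"{c:g}": len(g.edges) for c, g in analysis_graphs.items()},
        )

        # ---- stage 8: assignment + NJ contrast -----------------------------
        stage = "assign"
        labels = {s.seq_id: s.group for s in fres.kept}
        report = assign.assignment_report(
            base_graph,
            labels,
            list(config.analysis_cutoffs),
            state,
            tie_margin=config.tie_margin,
            provenance={
                "scheme": scheme.provenance(),
                "report_cutoff": config.report_cutoff,
                "rng_seed": config.rng_seed,
                "layout_seed": config.layout_seed,
            },
        )
        report.write_tsv(outdir / "connectivity.tsv")
        (outdir / "assignment.md").write_text(report.to_markdown())
        manifest.record(stage, parahox_groups=sorted(report.rankings))

        tree = None
        attraction = None
        if config.run_nj_contrast:
            stage = "nj_contrast"
            dm = njtree.domain_distance(fres.kept, model)
            tree = njtree.neighbor_joining(dm)
            (outdir / "nj.nwk").write_text(tree.newick + "\n")
            by_group: dict[str, list[str]] = {}
            for s in fres.kept:
                by_group.setdefault(s.group.name, []).append(s.seq_id)
            if len(by_group.get("Cdx", [])) >= 2 and len(by_group.get("posterior", [])) >= 2:
                attraction = njtree.attraction_check(
                    tree, by_group["Cdx"], by_group["posterior"]
                )
            manifest.record(
                stage,
                n_taxa=len(dm.labels),
                cdx_posterior_attracted=None if attraction is None else attraction.attracted,
            )

        manifest.status = "success"
        return PipelineResult(report, base_graph, state, manifest, tree, attraction)
    except Exception:
        manifest.status = "failed"
        manifest.failing_stage = stage
        raise
    finally:
        manifest.write(outdir)
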