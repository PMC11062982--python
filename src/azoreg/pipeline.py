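"""End-to-end orchestration: simulate -> meta -> coexpression -> screen ->
mapping -> qPCR, merged into one per-gene candidate-regulator report.

A single global seed deterministically derives one sub-seed per stage (by
hashing the stage name), so any stage can be re-run in isolation and the
whole pipeline is byte-reproducible. Every output file lands in the run
directory and is checksummed into ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression, compendium, io, mapping, qpcr, screen, simulate

ALL_STAGES = ("compendium", "coexpression", "screen", "mapping", "qpcr")

#: Gene names given to the first genes of the toy genome, so that screen hits,
#: insertion calls and qPCR folds converge on nameable candidate regulators.
REGULATOR_ANALOGS = ("arsC", "relA", "plsY", "trmM", "gshA", "glnE")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across processes)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    focal_gene: str = "azoR"
    k: int = 200
    alpha: float = 0.05
    cut_low: float = 65.0
    cut_high: float = 110.0
    e_cutoff: float = 1e-5
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    compendium_sim: simulate.CompendiumSimConfig | None = None
    screen_sim: simulate.ScreenSimConfig | None = None
    qpcr_sim: simulate.QpcrSimConfig | None = None
    mapping_sim: simulate.MapSimConfig | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("focal_gene", "k", "alpha", "cut_low", "cut_high",
                    "e_cutoff", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


@dataclass
class CandidateReport:
    """Per-gene evidence rows plus the focal gene's condition summary."""

    evidence: pd.DataFrame
    condition_summary: pd.DataFrame
    focal_gene: str = "azoR"

    def to_json(self) -> str:
        payload = {
            "focal_gene": self.focal_gene,
            "evidence": self.evidence.to_dict(orient="records"),
            "condition_summary": self.condition_summary.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "CandidateReport":
        raw = json.loads(text)
        ev_cols = EVIDENCE_COLUMNS
        return cls(
            pd.DataFrame(raw["evidence"], columns=ev_cols),
            pd.DataFrame(raw["condition_summary"]),
            raw["focal_gene"],
        )


EVIDENCE_COLUMNS = [
    "gene", "consensus_count", "screen_strain", "screen_class", "screen_p",
    "insertion_pos", "identity_pct", "coverage_pct", "qpcr_fold",
    "qpcr_condition", "sources",
]


@dataclass
class PipelineResult:
    report: CandidateReport
    manifest: dict
    outputs: dict[str, object] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the requested stages in dependency order and merge evidence.

    Simulation configs default to the package's study-scale settings, wired
    so the planted signals converge: the toy genome names its first genes
    after the regulator analogs that the screen's confirmed hits interrupt
    and the qPCR stage quantifies. Stage outputs are written under
    ``outdir`` and checksummed into the manifest.
    """
    if not config.stages:
        raise ValueError("nothing to run: no stages enabled")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, object] = {}
    evidence: dict[str, dict] = {}
    cond_summary = pd.DataFrame()

    def ev(gene: str) -> dict:
        return evidence.setdefault(
            gene, {c: None for c in EVIDENCE_COLUMNS} | {"gene": gene, "sources": []}
        )

    if "compendium" in config.stages or "coexpression" in config.stages:
        cfg = config.compendium_sim or simulate.CompendiumSimConfig(
            focal_gene=config.focal_gene, seed=stage_seed(config.seed, "compendium")
        )
        comp, comp_truth = simulate.gen_compendium(cfg)
        io.write_truth(comp_truth, outdir / "compendium_truth.json")
        filt = compendium.filter_compendium(comp, config.focal_gene, strain_pattern="K-12")
        outputs["filter_removed"] = filt.removed

    if "compendium" in config.stages:
        cond_summary = compendium.analyze_conditions(
            filt.compendium, config.focal_gene, alpha=config.alpha
        )
        io.write_tsv(cond_summary, outdir / "condition_summary.tsv")
        outputs["condition_summary"] = cond_summary

    if "coexpression" in config.stages:
        lists, skipped = coexpression.compendium_neighbor_lists(
            filt.compendium, config.focal_gene, config.k
        )
        table = coexpression.consensus_counts(lists)
        thr = coexpression.candidate_threshold(table)
        candidates = coexpression.select_candidates(table, thr)
        io.write_tsv(
            table.counts.rename("count").rename_axis("gene").reset_index(),
            outdir / "consensus_counts.tsv",
        )
        outputs.update(consensus=table, threshold=thr, candidates=candidates,
                       skipped_datasets=skipped)
        for g in candidates:
            row = ev(g)
            row["consensus_count"] = int(table.counts[g])
            row["sources"].append("coexpression")

    strain_to_gene: dict[str, str] = {}
    confirmed = pd.DataFrame()
    if "screen" in config.stages:
        cfg = config.screen_sim or simulate.ScreenSimConfig(
            seed=stage_seed(config.seed, "screen")
        )
        plates, screen_truth = simulate.gen_screen(cfg)
        io.write_plates(plates, outdir / "plates.csv")
        io.write_truth(screen_truth, outdir / "screen_truth.json")
        scored = screen.score_plates(plates, wt_strain=simulate.WT_STRAIN)
        called = screen.call_hits(scored, config.cut_low, config.cut_high)
        prelim = called[
            (called["hit_class"] != "neutral")
            & (called["strain"] != simulate.KO_CONTROL_STRAIN)
        ]["strain"].tolist()
        retest = simulate.gen_retest(
            cfg, screen_truth, prelim, seed=stage_seed(config.seed, "retest")
        )
        wt_reps = retest[retest["strain"] == simulate.WT_STRAIN]["decol_pct"]
        conf = screen.confirm_hits(
            retest[retest["strain"] != simulate.WT_STRAIN], wt_reps,
            config.alpha, config.cut_low, config.cut_high,
        )
        confirmed = conf[conf["confirmed"]].reset_index(drop=True)
        io.write_tsv(conf, outdir / "screen_confirmed.tsv")
        outputs.update(screen_called=called, screen_confirmed=conf,
                       screen_truth=screen_truth)

    if "mapping" in config.stages:
        n_ins = len(confirmed) if len(confirmed) else None
        cfg = config.mapping_sim or simulate.MapSimConfig(
            gene_names=REGULATOR_ANALOGS,
            n_insertions=n_ins or simulate.MapSimConfig().n_insertions,
            seed=stage_seed(config.seed, "mapping"),
        )
        sim, map_truth = simulate.gen_reference_and_reads(cfg)
        io.write_fasta([("ref", sim.genome)], outdir / "reference.fa")
        io.write_fasta(sim.reads, outdir / "reads.fa")
        io.write_annotations(sim.annotations, outdir / "annotations.tsv")
        io.write_truth(map_truth, outdir / "mapping_truth.json")
        # reads stand for the confirmed strains' junction products, in order
        read_strains = (
            dict(zip([r for r, _ in sim.reads], confirmed["strain"]))
            if len(confirmed)
            else {}
        )
        reports = mapping.map_reads(
            sim.reads, sim.genome, sim.annotations, e_cutoff=config.e_cutoff
        )
        io.write_tsv(mapping.insertion_table(reports), outdir / "insertions.tsv")
        io.write_tsv(mapping.to_bed(reports), outdir / "insertions.bed")
        outputs.update(insertion_reports=reports, mapping_truth=map_truth)
        for rep in reports:
            if rep.status != "mapped" or rep.gene == "intergenic":
                continue
            row = ev(rep.gene)
            row["insertion_pos"] = rep.insertion_pos
            row["identity_pct"] = rep.alignment.identity_pct
            row["coverage_pct"] = rep.alignment.query_coverage_pct
            row["sources"].append("mapping")
            strain = read_strains.get(rep.read_id)
            if strain is not None and len(confirmed):
                sel = confirmed[confirmed["strain"] == strain]
                if len(sel):
                    row["screen_strain"] = strain
                    row["screen_class"] = sel.iloc[0]["hit_class"]
                    row["screen_p"] = float(sel.iloc[0]["p_value"])
                    row["sources"].append("screen")

    if "qpcr" in config.stages:
        cfg = config.qpcr_sim or simulate.QpcrSimConfig(
            seed=stage_seed(config.seed, "qpcr")
        )
        ct, qpcr_truth = simulate.gen_qpcr(cfg)
        io.write_ct_table(ct, outdir / "ct_values.csv")
        io.write_truth(qpcr_truth, outdir / "qpcr_truth.json")
        folds = qpcr.all_fold_changes(ct, cfg.reference_gene, cfg.control_condition)
        io.write_tsv(folds, outdir / "fold_changes.tsv")
        outputs.update(fold_changes=folds, qpcr_truth=qpcr_truth)
        non_control = folds[folds["condition"] != cfg.control_condition]
        for gene, grp in non_control.groupby("target"):
            top = grp.loc[grp["fold_change"].idxmax()]
            row = ev(gene)
            row["qpcr_fold"] = float(top["fold_change"])
            row["qpcr_condition"] = str(top["condition"])
            row["sources"].append("qpcr")

    rows = []
    for g in sorted(evidence):
        row = dict(evidence[g])
        row["sources"] = ";".join(dict.fromkeys(row["sources"]))
        rows.append(row)
    report = CandidateReport(
        pd.DataFrame(rows, columns=EVIDENCE_COLUMNS), cond_summary, config.focal_gene
    )
    write_report(report, outdir / "candidate_report")

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(manifest, outdir / "manifest.json")
    return PipelineResult(report, manifest, outputs)


def write_report(report: CandidateReport, path_prefix: str | Path) -> list[Path]:
    """Write TSV and JSON renderings; the JSON round-trips losslessly."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")
    io.write_tsv(report.evidence, tsv)
    js.write_text(report.to_json())
    return [tsv, js]


def read_report(path_prefix: str | Path) -> CandidateReport:
    return CandidateReport.from_json(Path(path_prefix).with_suffix(".json").read_text())
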