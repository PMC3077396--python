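"""End-to-end orchestration: simulate -> qc -> linkage -> cascade -> cnv -> loh.

A run is driven by a :class:`RunConfig` (YAML round-trippable), executes the
enabled stages in order into a run directory, and writes a ``summary.json``
collecting the filter ledger, linkage intervals, CNV segments and LOH
results.  The log records the package version, seed and a hash of the
effective configuration, and re-running with the emitted config reproduces
all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .capture import design_summary, tile_probes
from .cnv import (DEL_THRESHOLD, MIN_WINDOWS, WINDOW_BP, call_segments,
                  log2_ratio, window_counts, write_segments_bed)
from .linkage import (DiseaseModel, extract_interval, lod_track, marker_qc,
                      max_attainable_lod, restrict_founders_affected,
                      write_lod_track)
from .loh import SubcloneCount, compare_tissues
from .readqc import coverage_stats, mark_duplicates, reads_to_tsv
from .syndata import Cohort, SimConfig, generate_cohort
from .variants import recurrence_across_families, run_cascade, write_vcf

log = logging.getLogger("famseq")

STAGES = ("simulate", "qc", "linkage", "cascade", "cnv", "loh")


class UserError(Exception):
    """A problem with the inputs or configuration (exit code 1)."""


@dataclass
class RunConfig:
    """Run-level configuration with the published defaults for every threshold."""
    seed: int = 0
    outdir: str = "famseq-run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: SimConfig = field(default_factory=SimConfig)
    # variant cascade
    min_quality: float = 20.0          # strict >, per the second-capture rule
    min_support: int = 3
    support_mode: str = "ge"           # first-array mode; 'gt' for second-array
    # linkage model
    disease_allele_freq: float = 1e-7
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)
    min_interval_cm: float | None = 1.0
    # cnv
    window_bp: int = WINDOW_BP
    del_threshold: float = DEL_THRESHOLD
    min_windows: int = MIN_WINDOWS
    # mlpa / loh
    mlpa_threshold: float = 0.8

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise UserError(f"unknown stage {s!r}; expected subset of {STAGES}")
        self.sim.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["penetrance"] = list(self.penetrance)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("sim") is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        if raw.get("penetrance") is not None:
            raw["penetrance"] = tuple(raw["penetrance"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(outdir: str) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    stream = logging.StreamHandler()
    filehandler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, filehandler):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict."""
    config.validate()
    config.sim.seed = config.seed
    os.makedirs(config.outdir, exist_ok=True)
    _setup_logging(config.outdir)
    log.info("famseq %s seed=%d config=%s", __version__, config.seed,
             config.config_hash())
    config.to_yaml(os.path.join(config.outdir, "config.yaml"))

    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash(), "stages": {}}
    enabled = set(config.stages)
    cohort: Cohort | None = None

    if "simulate" in enabled:
        cohort = generate_cohort(config.sim)
        cohort.truth.to_json(os.path.join(config.outdir, "truth.json"))
        for family, ped in cohort.pedigrees.items():
            ped.to_ped(os.path.join(config.outdir, f"{family}.ped"))
        reads_to_tsv(cohort.reads, os.path.join(config.outdir, "reads.tsv"))
        probes = tile_probes(cohort.targets)
        with open(os.path.join(config.outdir, "capture_design.json"), "w") as fh:
            json.dump(design_summary(cohort.targets, probes), fh, indent=2)
        summary["stages"]["simulate"] = {
            "n_families": len(cohort.pedigrees),
            "n_samples": int(cohort.reads["sample"].nunique()),
            "n_reads": int(len(cohort.reads)),
        }
        log.info("simulate: %d families, %d reads", len(cohort.pedigrees),
                 len(cohort.reads))
    else:
        summary["stages"]["simulate"] = "skipped"

    def need_cohort(stage: str) -> Cohort:
        if cohort is None:
            raise UserError(f"stage '{stage}' needs the simulate stage "
                            "(external inputs go through the stage CLIs)")
        return cohort

    if "qc" in enabled:
        c = need_cohort("qc")
        marked = mark_duplicates(c.reads)
        c.reads = marked
        pre = coverage_stats(marked, c.targets, dedup=False)
        post = coverage_stats(marked, c.targets, dedup=True)
        pre.to_tsv(os.path.join(config.outdir, "coverage_pre_dedup.tsv"))
        post.to_tsv(os.path.join(config.outdir, "coverage_post_dedup.tsv"))
        summary["stages"]["qc"] = {
            "mean_on_target": float(pre.per_sample["on_target_fraction"].mean()),
            "mean_ge_5x_pre": float(pre.per_sample["ge_5x"].mean()),
            "mean_ge_5x_post": float(post.per_sample["ge_5x"].mean()),
        }
        log.info("qc: on-target %.3f", summary["stages"]["qc"]["mean_on_target"])
    else:
        summary["stages"]["qc"] = "skipped"

    if "linkage" in enabled:
        c = need_cohort("linkage")
        from .syndata import simulate_marker_panel, substream

        model = DiseaseModel(q=config.disease_allele_freq,
                             penetrance=config.penetrance)
        results = {}
        # LOD track on the most informative family (mirrors a single-family scan)
        best_family = max(c.pedigrees, key=lambda f: len(c.pedigrees[f].affected))
        for family, ped in c.pedigrees.items():
            try:
                sub = restrict_founders_affected(ped)
            except Exception as exc:
                log.warning("linkage %s: %s", family, exc)
                continue
            entry = {
                "n_members_restricted": len(sub),
                "max_attainable_lod": round(max_attainable_lod(sub), 1),
            }
            if family == best_family and sub.n_meioses <= 22 and len(sub.affected) >= 2:
                panel, causal_bp = simulate_marker_panel(
                    sub, c.carriers[family],
                    substream(config.seed, "markers", family))
                panel, _ = marker_qc(panel, sub)
                if len(panel):
                    track = lod_track(sub, panel, model)
                    write_lod_track(
                        os.path.join(config.outdir, f"{family}.lod.tsv"), track)
                    intervals = extract_interval(track,
                                                 min_cm=config.min_interval_cm)
                    entry["causal_bp"] = causal_bp
                    entry["intervals"] = [iv.to_dict() for iv in intervals]
            results[family] = entry
        summary["stages"]["linkage"] = results
        log.info("linkage: %d families analyzed", len(results))
    else:
        summary["stages"]["linkage"] = "skipped"

    if "cascade" in enabled:
        c = need_cohort("cascade")
        per_family_candidates = {}
        ledgers = []
        for family, fam_calls in c.calls.items():
            carr = {s: c.truth.carriers[family][s] for s in fam_calls}
            ped = c.pedigrees[family]
            aff = {s: fam_calls[s] for s in fam_calls
                   if ped[s.split(".", 1)[1]].affection == "affected"}
            una = {s: fam_calls[s] for s in fam_calls if s not in aff}
            if not aff:
                continue
            candidates, ledger = run_cascade(
                family, aff, una, [c.catalog], min_q=config.min_quality,
                min_support=config.min_support, support_mode=config.support_mode)
            per_family_candidates[family] = candidates
            tab = ledger.table.copy()
            tab.insert(0, "family", family)
            ledgers.append(tab)
        if ledgers:
            pd.concat(ledgers).to_csv(
                os.path.join(config.outdir, "filter_ledger.tsv"), sep="\t")
        recurrence = recurrence_across_families(per_family_candidates)
        recurrence.to_json(os.path.join(config.outdir, "recurrence.json"),
                           orient="records", indent=2)
        flat = [v for vs in per_family_candidates.values() for v in vs]
        write_vcf(flat, os.path.join(config.outdir, "candidates.vcf"))
        top = recurrence.iloc[0].to_dict() if len(recurrence) else None
        summary["stages"]["cascade"] = {
            "candidates_per_family": {f: len(v) for f, v in
                                      per_family_candidates.items()},
            "top_gene": top,
        }
        log.info("cascade: top gene %s", top["gene"] if top else None)
    else:
        summary["stages"]["cascade"] = "skipped"

    if "cnv" in enabled:
        c = need_cohort("cnv")
        reads = c.reads if "duplicate" in c.reads else mark_duplicates(c.reads)
        windows = window_counts(reads, c.targets, window_bp=config.window_bp)
        samples = sorted(reads["sample"].unique())
        all_segments = []
        for s in samples:
            if len(samples) < 3:
                break
            ratios = log2_ratio(windows, s, samples)
            for seg in call_segments(ratios, del_threshold=config.del_threshold,
                                     min_windows=config.min_windows):
                all_segments.append((s, seg))
        write_segments_bed(os.path.join(config.outdir, "segments.bed"),
                           [seg for _, seg in all_segments])
        summary["stages"]["cnv"] = {
            "n_segments": len(all_segments),
            "segments": [{"sample": s, **seg.to_dict()}
                         for s, seg in all_segments],
        }
        log.info("cnv: %d segments", len(all_segments))
    else:
        summary["stages"]["cnv"] = "skipped"

    if "loh" in enabled:
        c = need_cohort("loh")
        lesion = SubcloneCount(k=c.subclone_counts["lesion"],
                               n=c.config.subclone_n, tissue="lesion")
        control = SubcloneCount(k=c.subclone_counts["control"],
                                n=c.config.subclone_n, tissue="control")
        comparison = compare_tissues(lesion, control)
        with open(os.path.join(config.outdir, "loh.json"), "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        summary["stages"]["loh"] = {
            "lesion_p": comparison.lesion.p_value,
            "control_p": comparison.control.p_value,
            "lesion_f_hat": comparison.lesion.f_hat,
        }
        log.info("loh: lesion p=%.3g f_hat=%.3f", comparison.lesion.p_value,
                 comparison.lesion.f_hat)
    else:
        summary["stages"]["loh"] = "skipped"

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
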