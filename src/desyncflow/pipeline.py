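"""End-to-end pipeline: simulate -> cosinor -> screen -> enrich -> coherence.

A run is driven by a :class:`RunConfig` (optionally loaded from YAML),
executes the requested stages in dependency order inside one output
directory, and writes a JSON manifest recording the seed, configuration and
SHA-256 checksum of every output file. Re-running with unchanged inputs
reuses stage outputs whose recorded checksums still match, so a run is both
reproducible (same seed => byte-identical outputs) and cheaply resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import cosinor, enrich, io, screen, simulate

ALL_STAGES = ("simulate", "fit_cosinor", "compare_rhythms", "screen",
              "enrich", "coherence", "report")

#: stage -> stages whose outputs it consumes
STAGE_DEPS = {
    "simulate": (),
    "fit_cosinor": ("simulate",),
    "compare_rhythms": ("fit_cosinor",),
    "screen": ("simulate", "fit_cosinor"),
    "enrich": ("simulate", "screen"),
    "coherence": ("simulate", "screen"),
    "report": ("compare_rhythms", "screen", "enrich", "coherence"),
}

#: stage -> output file names (within the run directory)
STAGE_OUTPUTS = {
    "simulate": ("expression_matrix.tsv", "sample_sheet.csv", "hormones.tsv",
                 "target_set.gmt", "truth_probes.tsv", "truth_hormones.tsv"),
    "fit_cosinor": ("cosinor_fits.tsv",),
    "compare_rhythms": ("rhythm_comparison.tsv",),
    "screen": ("screen_results.tsv", "aligned_design.tsv"),
    "enrich": ("enrichment.tsv",),
    "coherence": ("coherence.tsv", "lag_summary.tsv"),
    "report": ("report.txt", "report_summary.tsv"),
}


@dataclass
class RunConfig:
    """One source of truth for a pipeline run."""

    outdir: str = "desyncflow_run"
    seed: int = 0
    alpha: float = 0.05
    binning: str = "quantile"
    regulator: str = "SP1"
    stages: tuple = ALL_STAGES
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(seed=self.seed, **self.simulation)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Stage implementations (each reads/writes files in the run directory)
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, d: Path):
    study = simulate.simulate_study(cfg.simulation_config())
    io.write_expression(study.expression, d / "expression_matrix.tsv",
                        d / "sample_sheet.csv")
    io.write_hormones(study.hormones, d / "hormones.tsv")
    io.write_gene_sets([study.target_set], d / "target_set.gmt")
    simulate.write_truth(study.truth.probes, d / "truth_probes.tsv")
    simulate.write_truth(study.truth.hormones, d / "truth_hormones.tsv")


def _stage_fit_cosinor(cfg: RunConfig, d: Path):
    series = io.read_hormones(d / "hormones.tsv")
    fits = cosinor.fit_cohort(series)
    cosinor.write_fits(fits, d / "cosinor_fits.tsv")


def _stage_compare_rhythms(cfg: RunConfig, d: Path):
    fits = cosinor.read_fits(d / "cosinor_fits.tsv")
    frames = []
    for analyte in sorted({f.analyte for f in fits}):
        fin = {f.participant_id: f for f in fits
               if f.analyte == analyte and f.condition == io.IN_PHASE}
        fout = {f.participant_id: f for f in fits
                if f.analyte == analyte and f.condition == io.OUT_OF_PHASE}
        cmp = cosinor.compare_rhythms(fin, fout, analyte=analyte)
        frames.append(cosinor.comparison_to_frame(cmp))
    pd.concat(frames, ignore_index=True).to_csv(
        d / "rhythm_comparison.tsv", sep="\t", index=False, float_format="%.10g")


def _cortisol_peaks(d: Path) -> dict:
    fits = cosinor.read_fits(d / "cosinor_fits.tsv")
    return {f.participant_id: f for f in fits
            if f.analyte == io.CORTISOL and f.condition == io.IN_PHASE}


def _stage_screen(cfg: RunConfig, d: Path):
    data = io.read_expression(d / "expression_matrix.tsv", d / "sample_sheet.csv")
    design = screen.align_and_bin(data, _cortisol_peaks(d), binning=cfg.binning)
    design.table.to_csv(d / "aligned_design.tsv", sep="\t", index=False,
                        float_format="%.10g")
    results = screen.screen_all(data, design, alpha=cfg.alpha)
    screen.write_screen_results(results, d / "screen_results.tsv")


def _stage_enrich(cfg: RunConfig, d: Path):
    data = io.read_expression(d / "expression_matrix.tsv", d / "sample_sheet.csv")
    results = screen.read_screen_results(d / "screen_results.tsv")
    gene_sets = io.read_gene_sets(d / "target_set.gmt")
    background = data.platform_genes()
    table = enrich.enrich_all(results, gene_sets, background)
    enrich.write_enrichment(table, d / "enrichment.tsv")


def _stage_coherence(cfg: RunConfig, d: Path):
    data = io.read_expression(d / "expression_matrix.tsv", d / "sample_sheet.csv")
    results = screen.read_screen_results(d / "screen_results.tsv")
    table = coh.coherence_table(data, cfg.regulator,
                                screen_results=results, alpha=cfg.alpha)
    coh.write_coherence(table, d / "coherence.tsv")
    coh.lag_summary(table).to_csv(d / "lag_summary.tsv", sep="\t",
                                  index=False, float_format="%.10g")


def _stage_report(cfg: RunConfig, d: Path):
    lines = ["# desyncflow run summary", f"seed: {cfg.seed}", ""]
    summary_rows = []

    rc = pd.read_csv(d / "rhythm_comparison.tsv", sep="\t")
    lines.append("## Hormone rhythm comparison (out-of-phase vs in-phase)")
    for _, r in rc.iterrows():
        lines.append(
            f"{r['analyte']}: amplitude diff {r['mean_amplitude_diff']:+.3g} "
            f"+/- {r['se_amplitude_diff']:.3g} (p={r['p_amplitude']:.3g}); "
            f"peak diff {r['mean_peak_diff_h']:+.3g} "
            f"+/- {r['se_peak_diff_h']:.3g} h (p={r['p_peak']:.3g}); "
            f"n={int(r['n_pairs'])}")
        summary_rows.append({"section": "rhythm", "name": r["analyte"],
                             "value": r["mean_peak_diff_h"], "p": r["p_peak"]})
    lines.append("")

    sr = screen.read_screen_results(d / "screen_results.tsv")
    gs = io.read_gene_sets(d / "target_set.gmt")[0]
    ov = screen.overlap_with_set(sr, gs, alpha=cfg.alpha)
    lines.append("## Disruption screen")
    lines.append(f"probes tested: {len(sr)}; affected: {int(sr['affected'].sum())}")
    lines.append(
        f"target set {ov['set_name']}: {ov['n_affected']}/{ov['n_probes_in_set']} "
        f"affected ({ov['fraction_affected']:.1%}); main only "
        f"{ov['n_main_only']}, interaction only {ov['n_interaction_only']}, "
        f"both {ov['n_both']}")
    summary_rows.append({"section": "screen", "name": "n_affected",
                         "value": int(sr["affected"].sum()), "p": np.nan})
    lines.append("")

    et = pd.read_csv(d / "enrichment.tsv", sep="\t")
    lines.append("## Target enrichment among affected genes")
    for _, r in et.iterrows():
        lines.append(
            f"{r['set_name']}: k={int(r['n_affected_targets'])}, "
            f"K={int(r['n_targets'])}, n={int(r['n_affected'])}, "
            f"N={int(r['n_background'])}, fold={r['fold_enrichment']:.3g}, "
            f"p={r['p_hyper']:.3g}")
        summary_rows.append({"section": "enrich", "name": r["set_name"],
                             "value": r["fold_enrichment"], "p": r["p_hyper"]})
    lines.append("")

    ct = pd.read_csv(d / "coherence.tsv", sep="\t")
    ls = pd.read_csv(d / "lag_summary.tsv", sep="\t")
    lines.append("## Temporal coherence with regulator")
    for aff, grp in ct.groupby("affected"):
        label = "affected" if aff else "not affected"
        lines.append(
            f"{label}: n={len(grp)}, significant correlation in-phase "
            f"{int(grp['sig_corr_in'].sum())}, out-of-phase "
            f"{int(grp['sig_corr_out'].sum())}")
        summary_rows.append({"section": "coherence",
                             "name": f"sig_corr_in_{label}",
                             "value": int(grp["sig_corr_in"].sum()), "p": np.nan})
    for _, r in ls.iterrows():
        lines.append(
            f"lags [{r['quantity']}], affected={r['affected']}: circular mean "
            f"{r['circular_mean_h']:+.3g} h, concentration R="
            f"{r['resultant_length']:.3f} (n={int(r['n'])})")
    lines.append("")

    (d / "report.txt").write_text("\n".join(lines))
    pd.DataFrame(summary_rows).to_csv(d / "report_summary.tsv", sep="\t",
                                      index=False, float_format="%.10g")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit_cosinor": _stage_fit_cosinor,
    "compare_rhythms": _stage_compare_rhythms,
    "screen": _stage_screen,
    "enrich": _stage_enrich,
    "coherence": _stage_coherence,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stages are re-used when a previous manifest records matching checksums
    for all their inputs and outputs; a stage whose dependency was neither
    requested nor previously completed is an error naming the stage.
    """
    d = Path(cfg.outdir)
    d.mkdir(parents=True, exist_ok=True)
    manifest_path = d / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    requested = [s for s in ALL_STAGES if s in cfg.stages]
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    manifest = {"seed": cfg.seed, "config": dataclasses.asdict(cfg), "stages": {}}
    completed = set()

    def outputs_ok(stage):
        rec = previous.get(stage)
        if rec is None:
            return False
        for fname, digest in rec["outputs"].items():
            f = d / fname
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    for stage in requested:
        for dep in STAGE_DEPS[stage]:
            dep_done = dep in completed or outputs_ok(dep)
            if not dep_done:
                raise PipelineError(f"{stage} requires {dep} results")
        input_digest = {
            fname: _sha256(d / fname)
            for dep in STAGE_DEPS[stage] for fname in STAGE_OUTPUTS[dep]
        }
        rec = previous.get(stage)
        if (rec is not None and rec.get("inputs") == input_digest
                and rec.get("config_seed") == cfg.seed and outputs_ok(stage)):
            manifest["stages"][stage] = rec | {"reused": True}
            completed.add(stage)
            continue
        try:
            _STAGE_FUNCS[stage](cfg, d)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "inputs": input_digest,
            "outputs": {f: _sha256(d / f) for f in STAGE_OUTPUTS[stage]},
            "config_seed": cfg.seed,
            "reused": False,
        }
        completed.add(stage)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def summarise(outdir) -> str:
    """Return the plain-text report for a completed run."""
    report = Path(outdir) / "report.txt"
    if not report.exists():
        raise PipelineError("missing report: run the 'report' stage first")
    return report.read_text()
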