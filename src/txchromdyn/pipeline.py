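"""Manifest-driven orchestration of the analysis stages.

A run manifest (YAML or dict) names the stages to execute, a seed, an
output directory and optional per-stage parameter overrides.  Stages run in
dependency order (simulate -> annotate -> signal-derived stages); each
writes tab-delimited tables plus a ``summary.json``, and the run ends with
an ``index.json`` listing every output file with its SHA-256 checksum.
Re-running an identical manifest reproduces every output byte for byte.

Input paths default to the files the ``simulate`` stage writes, so a fully
synthetic end-to-end run needs nothing but a seed; any path can be
overridden to point at real data in the same formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import genome_model as gm
from . import nucleosome as nuc
from . import pausing_metrics as pm
from . import retention as ret
from . import synthetic_data as syn
from . import wavefront as wf
from .retention import CountTable
from .signal_engine import BinnedSignal, read_bed

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "annotate", "ei", "activity", "wave", "retention", "nuc"]
STAGE_DEPS = {
    "simulate": [],
    "annotate": [],
    "ei": ["annotate"],
    "activity": ["annotate"],
    "wave": [],
    "retention": [],
    "nuc": ["annotate"],
}


def load_manifest(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _require(path: Path, key: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"manifest input missing: {key} -> {path}")
    return path


class PipelineRun:
    def __init__(self, manifest: dict):
        self.manifest = manifest
        self.seed = int(manifest.get("seed", 0))
        self.outdir = Path(manifest["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.params = manifest.get("params", {}) or {}
        self.inputs = self.outdir / "inputs"
        self.failed: set[str] = set()

    # -- helpers -----------------------------------------------------------

    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _cfg(self) -> syn.SimulationConfig:
        overrides = dict(self.params.get("simulate", {}))
        overrides.pop("scenarios", None)
        cfg = syn.SimulationConfig(seed=self.seed, **overrides)
        return cfg

    def _path(self, stage: str, key: str, default: Path) -> Path:
        p = self.params.get(stage, {}).get(key)
        return _require(Path(p) if p else default, f"{stage}.{key}")

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> dict:
        cfg = self._cfg()
        self.inputs.mkdir(exist_ok=True)
        rng = np.random.default_rng(self.seed)
        genes, chrom_sizes = syn.make_genome(cfg, rng)
        gm.write_gene_table(genes, self.inputs / "transcripts.tsv")
        _dump_json(chrom_sizes, self.inputs / "chrom_sizes.json")

        reads, ei_truth = syn.simulate_chip_reads(cfg, genes, rng)
        for cond, df in reads.items():
            df.to_csv(self.inputs / f"reads_{cond}.bed", sep="\t",
                      header=False, index=False)
        ei_truth.to_csv(self.inputs / "truth_ei.tsv", sep="\t", index=False)

        for marks, p_hit in (("ser2p", 0.6), ("k27ac", 0.6), ("k27me3", 0.25)):
            peaks, truth = syn.simulate_peaks(genes, rng, p_hit=p_hit)
            pd.DataFrame([(p.chrom, p.start, p.end) for p in peaks]).to_csv(
                self.inputs / f"peaks_{marks}.bed", sep="\t",
                header=False, index=False)
            truth.to_csv(self.inputs / f"truth_peaks_{marks}.tsv", sep="\t",
                         index=False)

        for cell in cfg.wave_speed:
            mats, truth = syn.simulate_wave(cfg, cell_line=cell, rng=rng)
            for t, mat in mats.items():
                mat.to_csv(self.inputs / f"wave_{cell}_t{t:g}.tsv", sep="\t")
            truth.to_csv(self.inputs / f"truth_wave_{cell}.tsv", sep="\t",
                         index=False)

        for cell in cfg.retention_decay:
            nascent, chase, truth = syn.simulate_pulse_chase(
                cfg, cell_line=cell, rng=rng)
            nascent.counts.to_csv(self.inputs / f"counts_{cell}_nascent.tsv",
                                  sep="\t")
            for t, tab in chase.items():
                tab.counts.to_csv(self.inputs / f"counts_{cell}_chase{t:g}.tsv",
                                  sep="\t")
            truth.to_csv(self.inputs / f"truth_retention_{cell}.tsv", sep="\t",
                         index=False)

        for cell in cfg.nucleosome.positional_sd:
            frags, truth = syn.simulate_atac(cfg, genes, cell_line=cell, rng=rng)
            frags[["chrom", "start", "end"]].to_csv(
                self.inputs / f"fragments_{cell}.bed", sep="\t",
                header=False, index=False)
            truth.to_csv(self.inputs / f"truth_atac_{cell}.tsv", sep="\t",
                         index=False)

        with open(self.inputs / "config.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.seed, "config": cfg.as_dict()}, fh,
                           sort_keys=True)
        return {"n_genes": len(genes), "seed": self.seed}

    def stage_annotate(self) -> dict:
        p = self.params.get("annotate", {})
        transcripts = gm.read_gene_table(
            self._path("annotate", "transcripts", self.inputs / "transcripts.tsv"))
        clustered = gm.cluster_tss(transcripts, p.get("tss_radius", 50))
        kept = gm.filter_min_length(clustered, p.get("min_length", 2000))
        clear = gm.filter_clear_signal(kept, p.get("window_up", 250),
                                       p.get("window_down", 2000))
        d = self._stage_dir("annotate")
        gm.write_gene_table(kept, d / "genes.tsv")
        gm.write_gene_table(clear, d / "genes_ei.tsv")
        summary = {
            "n_transcripts": len(transcripts),
            "n_clustered": len(clustered),
            "n_min_length": len(kept),
            "n_clear_signal": len(clear),
        }
        _dump_json(summary, d / "summary.json")
        return summary

    def _ei_genes(self) -> list[gm.GeneModel]:
        return gm.read_gene_table(
            self._path("ei", "genes", self.outdir / "annotate" / "genes_ei.tsv"))

    def stage_ei(self) -> dict:
        p = self.params.get("ei", {})
        genes = self._ei_genes()
        control = read_bed(self._path("ei", "control_reads",
                                      self.inputs / "reads_NOUV.bed"))
        treated = read_bed(self._path("ei", "treated_reads",
                                      self.inputs / "reads_UV.bed"))
        mode = p.get("density_mode", "count")
        ei_c = pm.compute_ei(control, genes, density_mode=mode)
        ei_t = pm.compute_ei(treated, genes, density_mode=mode)
        deltas = pm.compute_delta_ei(ei_c, ei_t)
        d = self._stage_dir("ei")
        pm.ei_table(ei_c).to_csv(d / "ei_control.tsv", sep="\t", index=False)
        pm.ei_table(ei_t).to_csv(d / "ei_treated.tsv", sep="\t", index=False)
        pm.delta_ei_table(deltas).to_csv(d / "delta_ei.tsv", sep="\t", index=False)
        summary = {
            "n_genes": len(genes),
            "n_ei_control": len(ei_c),
            "n_ei_treated": len(ei_t),
            "n_delta": len(deltas),
            "percent_increased": pm.percent_increased(deltas),
            "density_mode": mode,
        }
        _dump_json(summary, d / "summary.json")
        return summary

    def stage_activity(self) -> dict:
        genes = gm.read_gene_table(
            self._path("activity", "genes", self.outdir / "annotate" / "genes.tsv"))
        peak_sets = {
            name: gm.read_peaks(self._path("activity", name,
                                           self.inputs / f"peaks_{name}.bed"))
            for name in ("ser2p", "k27ac", "k27me3")
        }
        labels = pm.classify_activity(genes, peak_sets["ser2p"],
                                      peak_sets["k27ac"], peak_sets["k27me3"])
        d = self._stage_dir("activity")
        pd.DataFrame(sorted(labels.items()),
                     columns=["gene_id", "activity"]).assign(
            activity=lambda x: x["activity"].map(lambda a: a.value)
        ).to_csv(d / "activity.tsv", sep="\t", index=False)
        counts = {a.value: 0 for a in pm.Activity}
        for lab in labels.values():
            counts[lab.value] += 1
        summary = {"n_genes": len(genes), "counts": counts}
        _dump_json(summary, d / "summary.json")
        return summary

    def stage_wave(self) -> dict:
        cfg = self._cfg()
        p = self.params.get("wave", {})
        bin_size = p.get("bin_size", 100)
        d = self._stage_dir("wave")
        summary: dict[str, Any] = {"cell_lines": {}}
        front_rows = []
        for cell in p.get("cell_lines", list(cfg.wave_speed)):
            fronts_by_t: dict[float, list[wf.WaveFront]] = {}
            for t in p.get("timepoints", list(cfg.timepoints_min)):
                path = self._path("wave", f"matrix_{cell}_{t:g}",
                                  self.inputs / f"wave_{cell}_t{t:g}.tsv")
                mat = pd.read_csv(path, sep="\t", index_col=0)
                signals = [
                    BinnedSignal(gid, bin_size, row.to_numpy(float))
                    for gid, row in mat.iterrows()
                ]
                params, fronts = wf.fit_and_call(signals, timepoint=t)
                fronts_by_t[t] = fronts
                front_rows.extend(
                    (cell, f.gene_id, t, f.front_bp, f.censored) for f in fronts)
            summary_df = wf.wave_summary(fronts_by_t)
            summary_df.to_csv(d / f"wave_summary_{cell}.tsv", sep="\t", index=False)
            speed = wf.estimate_speed(summary_df, cell_line=cell)
            summary["cell_lines"][cell] = {
                "speed_kb_per_min": speed.speed,
                "intercept_kb": speed.intercept,
                "n_timepoints": speed.n_timepoints,
                "n_censored": int(summary_df["n_censored"].sum()),
            }
        pd.DataFrame(front_rows, columns=["cell_line", "gene_id", "timepoint",
                                          "front_bp", "censored"]).to_csv(
            d / "fronts.tsv", sep="\t", index=False)
        _dump_json(summary, d / "summary.json")
        return summary

    def stage_retention(self) -> dict:
        cfg = self._cfg()
        p = self.params.get("retention", {})
        timepoints = p.get("timepoints", list(cfg.chase_timepoints_h))
        cells = p.get("cell_lines", list(cfg.retention_decay))
        tables: dict[str, dict] = {}
        for cell in cells:
            nascent = ret.read_count_table(
                self._path("retention", f"nascent_{cell}",
                           self.inputs / f"counts_{cell}_nascent.tsv"),
                f"{cell}_nascent")
            chase = {
                t: ret.read_count_table(
                    self._path("retention", f"chase_{cell}_{t:g}",
                               self.inputs / f"counts_{cell}_chase{t:g}.tsv"),
                    f"{cell}_chase{t:g}")
                for t in timepoints
            }
            # explicit nominal library size: depth-equalized synthetic libraries
            for tab in [nascent, *chase.values()]:
                tab.library_size = cfg.library_size
            tables[cell] = {"nascent": nascent, "chase": chase}
        universe = ret.median_activity_filter(
            [t["nascent"] for t in tables.values()]
            + [c for t in tables.values() for c in t["chase"].values()])
        d = self._stage_dir("retention")
        summary: dict[str, Any] = {"n_genes": len(universe), "tests": {}}
        records: dict[str, dict[float, list[ret.RetentionRecord]]] = {}
        rows = []
        for cell, tabs in tables.items():
            records[cell] = {}
            for t in timepoints:
                rec = ret.compute_retention(tabs["chase"][t], tabs["nascent"],
                                            universe, t)
                records[cell][t] = rec
                rows.extend((cell, r.gene_id, t, r.retention) for r in rec)
                summary.setdefault("median_retention", {}).setdefault(cell, {})[
                    f"{t:g}"] = float(np.median([r.retention for r in rec]))
        if len(cells) == 2:
            a, b = cells
            for t in timepoints:
                res = ret.permutation_t_test_iqr(
                    [r.retention for r in records[a][t]],
                    [r.retention for r in records[b][t]],
                    seed=self.seed)
                summary["tests"][f"{a}_vs_{b}_{t:g}h"] = res.as_dict()
        pd.DataFrame(rows, columns=["cell_line", "gene_id", "timepoint",
                                    "retention"]).to_csv(
            d / "retention.tsv", sep="\t", index=False)
        _dump_json(summary, d / "summary.json")
        return summary

    def stage_nuc(self) -> dict:
        cfg = self._cfg()
        p = self.params.get("nuc", {})
        genes = gm.read_gene_table(
            self._path("nuc", "genes", self.outdir / "annotate" / "genes.tsv"))
        d = self._stage_dir("nuc")
        cells = p.get("cell_lines", list(cfg.nucleosome.positional_sd))
        summary: dict[str, Any] = {"cell_lines": {}}
        vplots = {}
        for cell in cells:
            frags = nuc.fragments_from_bed(
                self._path("nuc", f"fragments_{cell}",
                           self.inputs / f"fragments_{cell}.bed"))
            calls = nuc.call_dyads(frags, genes,
                                   search_downstream=p.get("search_downstream", 250))
            pd.DataFrame(
                [(c.gene_id, c.position, c.offset_from_tss, c.occupancy,
                  c.fuzziness, c.n_fragments) for c in calls],
                columns=["gene_id", "position", "offset_from_tss", "occupancy",
                         "fuzziness", "n_fragments"]).to_csv(
                d / f"dyads_{cell}.tsv", sep="\t", index=False)
            # anchor Vplots on the called +1 (most TSS-proximal) dyads
            plus1 = {}
            for c in sorted(calls, key=lambda c: c.offset_from_tss):
                plus1.setdefault(c.gene_id, c)
            gene_by_id = {g.gene_id: g for g in genes}
            anchors = pd.DataFrame(
                [(gene_by_id[gid].chrom, c.position, gene_by_id[gid].strand)
                 for gid, c in plus1.items()],
                columns=["chrom", "pos", "strand"])
            vp = nuc.build_vplot(frags, anchors)
            vp.save(d / f"vplot_{cell}.tsv")
            vplots[cell] = vp.to_density()
            wide = nuc.call_dyads(frags, genes, search_downstream=1000)
            dyads_df = pd.DataFrame(
                [(c.gene_id, c.position) for c in wide],
                columns=["gene_id", "pos"])
            dyads_df["chrom"] = dyads_df["gene_id"].map(
                lambda g: gene_by_id[g].chrom)
            spacing = nuc.spacing_mode(dyads_df, genes, cell_line=cell)
            summary["cell_lines"][cell] = {
                "n_dyad_calls": len(calls),
                "median_fuzziness": float(np.median([c.fuzziness for c in calls]))
                if calls else None,
                "spacing_modes": {f"+{s.rank}": s.mode_distance for s in spacing},
            }
        if len(cells) == 2:
            a, b = cells
            diff = nuc.subtract_vplots(vplots[a], vplots[b])
            diff.save(d / f"vplot_{a}_minus_{b}.tsv")
            summary["flatten_test"] = nuc.vplot_flatten_test(
                vplots[a], vplots[b]).as_dict()
            summary["mono_band_test"] = nuc.mononucleosome_band_test(
                vplots[a], vplots[b]).as_dict()
        _dump_json(summary, d / "summary.json")
        return summary

    # -- driver ------------------------------------------------------------

    def run(self) -> Path:
        stages = self.manifest.get("stages", STAGE_ORDER)
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        results: dict[str, Any] = {}
        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            if any(dep in self.failed for dep in STAGE_DEPS[stage]):
                logger.warning("skipping %s: dependency failed", stage)
                self.failed.add(stage)
                continue
            try:
                results[stage] = getattr(self, f"stage_{stage}")()
            except FileNotFoundError:
                raise
            except Exception as exc:  # stage failure halts dependents only
                logger.error("stage %s failed: %s", stage, exc)
                self.failed.add(stage)
                results[stage] = {"error": str(exc)}
        self._write_index(results)
        return self.outdir

    def _write_index(self, results: dict) -> None:
        files = {}
        for f in sorted(self.outdir.rglob("*")):
            if f.is_file() and f.name != "index.json":
                files[str(f.relative_to(self.outdir))] = hashlib.sha256(
                    f.read_bytes()).hexdigest()
        _dump_json(
            {"seed": self.seed, "stages": results, "failed": sorted(self.failed),
             "files": files},
            self.outdir / "index.json")


def run_pipeline(manifest) -> Path:
    """Execute the requested stages; returns the run directory."""
    return PipelineRun(load_manifest(manifest)).run()
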