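"""End-to-end study pipeline: simulate -> screen -> select -> fit -> sensitivity
-> summarise, driven by one YAML config with a manifest for resumability.

Stage order mirrors the analysis workflow: multicollinearity screening first,
then covariance-structure selection over the full covariate set, optional
backward covariate selection, the final spatial fit, the prior-sensitivity
sweep, and the descriptive/risk-map summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ModelSpec, build_design
from .diagnostics import compute_gvif, descriptive_table, district_risk_map
from .graphs import AdjacencyGraph
from .model import SpatialLogit
from .selection import backward_select, sensitivity_sweep, structure_ladder
from .simulate import default_true_parameters, simulate_survey
from .graphs import generate_lattice_graph

__all__ = ["ConfigError", "StageError", "PipelineConfig", "Pipeline", "run_pipeline"]

log = logging.getLogger("spatlogit")

STAGES = ("simulate", "screen", "select", "fit", "sensitivity", "summarize")


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any compute)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    dataset_path: Path | None
    graph_path: Path | None
    simulate: dict | None
    model: ModelSpec
    sampler: dict
    selection: dict
    sensitivity: dict
    summaries: dict
    seed: int
    raw: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict, outdir=None, seed=None) -> "PipelineConfig":
        if not isinstance(cfg, dict):
            raise ConfigError("config must be a mapping")
        paths = cfg.get("paths", {})
        out = Path(outdir or paths.get("outdir") or "spatlogit_out")
        sim = cfg.get("simulate")
        dataset = paths.get("dataset")
        graph = paths.get("graph")
        if sim is None and dataset is None:
            raise ConfigError("either a simulate block or paths.dataset is required")
        if sim is None and graph is None:
            raise ConfigError("paths.graph is required when not simulating")
        if "model" not in cfg:
            raise ConfigError("config needs a model block")
        try:
            model = ModelSpec.from_dict(cfg["model"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid model block: {exc}") from exc
        sampler = dict(cfg.get("sampler", {}))
        master = sampler.pop("seed", 0) if seed is None else seed
        try:
            master = int(master)
        except (TypeError, ValueError):
            raise ConfigError("sampler.seed must be an integer") from None
        selection = dict(cfg.get("selection", {}))
        summaries = dict(cfg.get("summaries", {}))
        cutoff = float(summaries.get("exceedance_cutoff", 0.9))
        if not 0 < cutoff < 1:
            raise ConfigError("summaries.exceedance_cutoff must lie in (0, 1)")
        summaries["exceedance_cutoff"] = cutoff
        return cls(
            outdir=out,
            dataset_path=Path(dataset) if dataset else None,
            graph_path=Path(graph) if graph else None,
            simulate=sim,
            model=model,
            sampler=sampler,
            selection=selection,
            sensitivity=dict(cfg.get("sensitivity", {})),
            summaries=summaries,
            seed=master,
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        try:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from exc
        return cls.from_dict(cfg or {}, outdir=outdir, seed=seed)


class Pipeline:
    """Executes the staged workflow, writing a manifest as stages complete."""

    def __init__(self, config: PipelineConfig, force: bool = False):
        self.config = config
        self.force = force
        self.outdir = config.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()
        self._data = None
        self._graph = None
        self._results = None
        self._final_spec = config.model
        seq = np.random.SeedSequence(config.seed)
        self._stage_seeds = {
            s: int(c.generate_state(1)[0] % (2**31 - 1))
            for s, c in zip(STAGES, seq.spawn(len(STAGES)))
        }

    # -- manifest ----------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists() and not self.force:
            with open(self.manifest_path) as fh:
                return json.load(fh)
        return {"seed": self.config.seed, "stages": {}}

    def _record(self, stage: str, files: dict, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "files": files,
            "seed": self._stage_seeds[stage],
            "wall_time_s": round(time.time() - t0, 3),
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1)

    def _done(self, stage: str) -> bool:
        if self.force:
            return False
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() for p in entry["files"].values())

    # -- inputs ------------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        if self._data is None:
            path = self.config.dataset_path or self.outdir / "survey.csv"
            if not path.exists():
                raise FileNotFoundError(
                    f"dataset {path} not found; run the simulate stage or point "
                    f"paths.dataset at an existing file"
                )
            self._data = pd.read_csv(path)
        return self._data

    @property
    def graph(self) -> AdjacencyGraph:
        if self._graph is None:
            path = self.config.graph_path or self.outdir / "survey_graph.csv"
            self._graph = AdjacencyGraph.from_edge_csv(path)
        return self._graph

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> dict:
        cfg = self.config.simulate or {}
        graph = generate_lattice_graph(int(cfg.get("n_rows", 8)),
                                       int(cfg.get("n_cols", 8)))
        truth_kw = {k: cfg[k] for k in ("sigma_b", "sigma_h", "intercept")
                    if k in cfg}
        ds = simulate_survey(
            graph=graph,
            truth=default_true_parameters(**truth_kw),
            n_per_district=int(cfg.get("n_per_district", 278)),
            weight_scheme=cfg.get("weight_scheme", "stratified"),
            seed=self._stage_seeds["simulate"],
        )
        files = ds.write(self.outdir)
        self._data, self._graph = ds.data, ds.graph
        return files

    def stage_screen(self) -> dict:
        covs = self.config.raw.get("screen", {}).get("covariates")
        if covs is None:
            covs = [f.name for f in self.config.model.fixed_effects]
            covs += [t.name for t in self.config.model.smooth_terms]
        report = compute_gvif(self.data, covs)
        path = self.outdir / "gvif.csv"
        report.to_csv(path)
        return {"gvif": str(path)}

    def stage_select(self) -> dict:
        files = {}
        sel = self.config.selection
        spec = self.config.model
        if sel.get("ladder", True):
            report = structure_ladder(
                self.data, self.graph, spec,
                sampler=self.config.sampler, seed=self._stage_seeds["select"],
            )
            path = self.outdir / "ladder.csv"
            report.to_dataframe().to_csv(path)
            files["ladder"] = str(path)
            self._final_spec = spec.with_structure(report.best)
            tpath = self.outdir / "ladder_trace.json"
            with open(tpath, "w") as fh:
                json.dump({"best": report.best, "trace": report.decision_trace,
                           "warnings": report.warnings}, fh, indent=1)
            files["ladder_trace"] = str(tpath)
        if sel.get("backward", False):
            report = backward_select(
                self.data, self.graph, self._final_spec,
                sampler=self.config.sampler,
                seed=self._stage_seeds["select"] + 1,
                threshold=float(sel.get("threshold", 2.0)),
            )
            path = self.outdir / "backward_trace.json"
            with open(path, "w") as fh:
                json.dump({"selected": report.best,
                           "trace": report.decision_trace}, fh, indent=1)
            files["backward_trace"] = str(path)
            self._final_spec = report.selected_spec
        spec_path = self.outdir / "final_spec.json"
        with open(spec_path, "w") as fh:
            json.dump(self._final_spec.to_dict(), fh, indent=1)
        files["final_spec"] = str(spec_path)
        return files

    def _load_final_spec(self) -> ModelSpec:
        spec_path = self.outdir / "final_spec.json"
        if spec_path.exists():
            with open(spec_path) as fh:
                return ModelSpec.from_dict(json.load(fh))
        return self.config.model

    def stage_fit(self) -> dict:
        spec = self._final_spec = self._load_final_spec()
        model = SpatialLogit.from_dataframe(self.data, spec, self.graph)
        s = self.config.sampler
        res = model.fit(
            draws=int(s.get("draws", 500)),
            warmup=int(s.get("warmup", 300)),
            chains=int(s.get("chains", 2)),
            seed=self._stage_seeds["fit"],
        )
        self._results = res
        files = res.save(self.outdir / "fit")
        w = res.waic()
        wpath = self.outdir / "fit" / "waic.json"
        with open(wpath, "w") as fh:
            json.dump({"waic": w.waic, "p_d": w.p_d, "lppd": w.lppd}, fh, indent=1)
        files["waic"] = str(wpath)
        return files

    def _ensure_results(self):
        if self._results is None:
            self.stage_fit()
        return self._results

    def stage_sensitivity(self) -> dict:
        spec = self._load_final_spec()
        fams = self.config.sensitivity.get("families",
                                           ["gamma", "half_normal", "pc"])
        table = sensitivity_sweep(
            self.data, self.graph, spec, families=fams,
            sampler=self.config.sampler, seed=self._stage_seeds["sensitivity"],
        )
        path = self.outdir / "sensitivity.csv"
        table.to_csv(path, index=False)
        return {"sensitivity": str(path)}

    def stage_summarize(self) -> dict:
        files = {}
        desc = descriptive_table(self.data)
        dpath = self.outdir / "descriptive.csv"
        desc.to_csv(dpath)
        files["descriptive"] = str(dpath)
        res = self._ensure_results()
        if res.model.spec.has_car:
            cutoff = self.config.summaries.get("exceedance_cutoff", 0.9)
            risk = district_risk_map(res, cutoff=cutoff)
            rpath = self.outdir / "risk_map.csv"
            risk.to_csv(rpath)
            files["risk_map"] = str(rpath)
        return files

    # -- driver ------------------------------------------------------------
    def run(self, stages=None) -> dict:
        """Run the requested stages in order; skip completed ones unless forced."""
        if stages is None:
            stages = [s for s in STAGES
                      if s != "simulate" or self.config.simulate is not None]
        for stage in stages:
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
            if self._done(stage):
                log.info("stage %s: already complete, skipping", stage)
                continue
            log.info("stage %s: running", stage)
            t0 = time.time()
            try:
                files = getattr(self, f"stage_{stage}")()
            except (ConfigError,):
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc
            self._record(stage, files, t0)
        return self.manifest


def run_pipeline(config: PipelineConfig, force: bool = False, stages=None) -> dict:
    """Execute the pipeline and return the manifest of produced artifacts."""
    return Pipeline(config, force=force).run(stages)
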