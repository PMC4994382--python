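"""Stage orchestration: simulate -> describe -> kde -> fit, with manifests.

Each stage reads its declared inputs from the run directory, writes its
declared outputs there, and drops a machine-readable manifest (config
hash, seed, package versions, row counts) sufficient to reproduce the run
byte-for-byte.  One seed lives in the config; each stage derives its own
stream by stable hashing so stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjacency import build_adjacency
from .descriptive import choropleth_export, prevalence_by_admin, prevalence_table
from .kde import band_prevalence_surface, surface_to_csv, write_ascii_grid
from .model import McmcConfig, ModelSpec, export_posterior, fit_bym, summarise_posterior
from .survey_io import BANDS, SurveyDataset, load_survey, outcome_counts, write_survey
from .synthetic import SyntheticConfig, simulate_survey

log = logging.getLogger("prevmap")


class MissingInputError(FileNotFoundError):
    """A stage input artifact is absent; the message names it."""


class ConfigSchemaError(ValueError):
    """The pipeline config violates its schema; the message names the field."""


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "prevmap_run"
    bands: list[str] = field(default_factory=lambda: list(BANDS))
    cumulative: bool = False
    synthetic: dict = field(default_factory=dict)
    describe: dict = field(default_factory=dict)
    kde: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigSchemaError("config root must be a mapping")
        if "seed" not in doc:
            raise ConfigSchemaError("seed: field is mandatory")
        known = set(cls.__dataclass_fields__)
        extra = set(doc) - known
        if extra:
            raise ConfigSchemaError(f"unknown config keys {sorted(extra)}")
        cfg = cls(**doc)
        bad = set(cfg.bands) - set(BANDS)
        if bad:
            raise ConfigSchemaError(f"bands: unknown codes {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        return {"seed": self.seed, "out_dir": self.out_dir,
                "bands": list(self.bands), "cumulative": self.cumulative,
                "synthetic": dict(self.synthetic),
                "describe": dict(self.describe), "kde": dict(self.kde),
                "model": dict(self.model)}

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing input artifact: {path}")
    return path


def _manifest(cfg: PipelineConfig, stage: str, out: Path,
              counts: dict[str, int], t0: float) -> None:
    doc = {"stage": stage, "config_hash": cfg.config_hash(),
           "seed": cfg.seed, "stage_seed": cfg.stage_seed(stage),
           "prevmap_version": __version__,
           "numpy_version": np.__version__,
           "pandas_version": pd.__version__,
           "row_counts": counts,
           "elapsed_s": round(time.time() - t0, 3)}
    (out / f"manifest_{stage}.json").write_text(json.dumps(doc, indent=2))


def _load(out: Path) -> SurveyDataset:
    return load_survey(_require(out / "respondents.csv"),
                       _require(out / "clusters.csv"),
                       _require(out / "boundaries.geojson"))


def run_simulate(cfg: PipelineConfig) -> SurveyDataset:
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sdoc = dict(cfg.synthetic)
    sdoc.setdefault("seed", cfg.stage_seed("simulate"))
    scfg = SyntheticConfig.from_dict(sdoc)
    ds, truth = simulate_survey(scfg)
    write_survey(ds, out / "respondents.csv", out / "clusters.csv",
                 out / "boundaries.geojson")
    truth.to_csv(out / "truth.csv", index=False)
    log.info("simulate: %d respondents, %d clusters, %d districts",
             len(ds.respondents), len(ds.clusters), len(ds.districts))
    _manifest(cfg, "simulate", out,
              {"respondents": len(ds.respondents),
               "clusters": len(ds.clusters),
               "districts": len(ds.districts)}, t0)
    return ds


def run_describe(cfg: PipelineConfig) -> pd.DataFrame:
    t0 = time.time()
    out = Path(cfg.out_dir)
    ds = _load(out)
    level = int(cfg.describe.get("admin_level", 1))
    frames = []
    for band in cfg.bands:
        est = prevalence_by_admin(ds, band, admin_level=level)
        est.insert(1, "band", band)
        frames.append(est.rename(columns={"group": "unit_id"}))
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(out / "prevalence_by_unit.csv", index=False)

    r = ds.respondents.merge(ds.clusters[["cluster_id", "district_id"]],
                             on="cluster_id")
    parent = {u.unit_id: u.parent_id for u in ds.districts}
    labels = (r["district_id"].map(parent) if level == 1
              else r["district_id"])
    table = prevalence_table(ds, labels)
    table.to_csv(out / "prevalence_table.csv")

    units = ds.regions if level == 1 else ds.districts
    choropleth_export(units, long, out / "choropleth.geojson")
    log.info("describe: %d unit x band estimates at level %d",
             len(long), level)
    _manifest(cfg, "describe", out, {"estimates": len(long)}, t0)
    return long


def run_kde(cfg: PipelineConfig) -> dict:
    t0 = time.time()
    out = Path(cfg.out_dir)
    ds = _load(out)
    k = cfg.kde
    surfaces = {}
    counts = {}
    for band in cfg.bands:
        surf, bw, _grid = band_prevalence_surface(
            ds, band,
            n_opt=k.get("n_opt"),
            cell_size_km=float(k.get("cell_size_km", 5.0)),
            kernel=k.get("kernel", "gaussian"),
            weighted=bool(k.get("weighted", True)),
            support_floor=k.get("support_floor"))
        write_ascii_grid(surf, out / f"surface_{band}.asc")
        surface_to_csv(surf, out / f"surface_{band}.csv")
        bw.to_csv(out / f"bandwidths_{band}.csv", index=False)
        surfaces[band] = surf
        counts[f"cells_{band}"] = int(surf.mask.sum())
        log.info("kde %s: %dx%d grid, %d supported cells", band,
                 surf.grid.n_rows, surf.grid.n_cols, surf.mask.sum())
    _manifest(cfg, "kde", out, counts, t0)
    return surfaces


def run_fit(cfg: PipelineConfig) -> dict:
    t0 = time.time()
    out = Path(cfg.out_dir)
    ds = _load(out)
    m = cfg.model
    level = int(m.get("admin_level", 2))
    units = ds.districts if level == 2 else ds.regions
    graph = build_adjacency(units, island_policy=m.get("island_policy",
                                                       "join_nearest"))
    spec = ModelSpec(
        beta0_prior_sd=float(m.get("beta0_prior_sd", 10.0)),
        tau_u_shape=float(m.get("tau_u_shape", 1.0)),
        tau_u_rate=float(m.get("tau_u_rate", 0.01)),
        tau_v_shape=float(m.get("tau_v_shape", 1.0)),
        tau_v_rate=float(m.get("tau_v_rate", 0.01)))
    results = {}
    counts = {}
    for band in cfg.bands:
        tab = outcome_counts(ds, level, band, cumulative=cfg.cumulative)
        tab = tab.set_index("unit_id").reindex(graph.ids)
        mc = McmcConfig(n_iter=int(m.get("n_iter", 6000)),
                        n_burn=int(m.get("n_burn", 2000)),
                        thin=int(m.get("thin", 2)),
                        seed=(cfg.stage_seed("fit")
                              + list(BANDS).index(band)) % (2 ** 31))
        fit = fit_bym(tab["y"].to_numpy(), tab["n"].to_numpy(), graph,
                      spec, mc)
        summary = summarise_posterior(fit)
        export_posterior(summary, units, out / f"posterior_{band}.csv",
                         out / f"posterior_{band}.geojson", band=band)
        if m.get("save_draws"):
            pd.DataFrame(fit.p_draws, columns=fit.ids).to_csv(
                out / f"draws_{band}.csv", index=False)
        results[band] = summary
        counts[f"districts_{band}"] = len(summary)
        log.info("fit %s: %d units, mean posterior SD %.4f", band,
                 len(summary), summary["sd"].mean())
    _manifest(cfg, "fit", out, counts, t0)
    return results


STAGES = {"simulate": run_simulate, "describe": run_describe,
          "kde": run_kde, "fit": run_fit}


def run(subcommand: str, cfg: PipelineConfig):
    """Run one stage, or ``all`` = simulate -> describe -> kde -> fit."""
    if subcommand == "all":
        out = {}
        for name in ("simulate", "describe", "kde", "fit"):
            out[name] = STAGES[name](cfg)
        return out
    if subcommand not in STAGES:
        raise ConfigSchemaError(f"unknown stage {subcommand!r}")
    return STAGES[subcommand](cfg)
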