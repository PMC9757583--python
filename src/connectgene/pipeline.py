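"""End-to-end pipeline: synthetic world (or user inputs) -> SDM ensemble ->
resistance surface -> least-cost / circuit distances -> Mantel tests ->
thresholded habitat networks -> scale selection -> priority nodes.

Configuration defaults equal the study-design values wherever the design
prints one: 10,000 background points, 70-30 split, 10-fold CV with AUC >
0.75 and TSS > 0.4 gates, cost anchors 100/40/15/5/2/1, road cost 10,000,
committee cutoff 0.5, network thresholds 5,000-25,000 in steps of 5,000
capped at 250,000, 10,000 Mantel permutations, priority quantile 0.05 and
capacity exponent beta = 0.  A single master seed determines every
stochastic stage through a documented seed-derivation scheme.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DistanceMatrix, PointSet, derive_seed
from .costdist import build_lattice, lcd_matrix
from .circuit import ibr_matrix
from .genetics import mantel_test, select_scale
from .network import (
    assign_population_nodes,
    build_threshold_graph,
    cfbc,
    extract_habitat_nodes,
    prioritize_nodes,
)
from .resistance import DEFAULT_ANCHORS, DEFAULT_ROAD_COST, compose_resistance
from .sdm import (
    MODEL_KINDS,
    committee_ensemble,
    cross_validate_select,
    evaluate_predictions,
    extract_covariates,
    fit_sdm,
    importance_table,
    sample_background,
    split_train_test,
    _max_sss_threshold,
)
from .synthetic import SyntheticWorld, WorldParams, generate_world

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults are the study-design values."""

    seed: int = 0
    world: WorldParams = field(default_factory=WorldParams)
    n_background: int = 10000
    train_fraction: float = 0.7
    cv_folds: int = 10
    auc_gate: float = 0.75
    tss_gate: float = 0.4
    model_kinds: tuple[str, ...] = MODEL_KINDS
    model_settings: dict = field(default_factory=dict)
    importance_repeats: int = 10
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    road_cost: float = DEFAULT_ROAD_COST
    cost_mode: str = "interpolate"
    ensemble_cutoff: float = 0.5
    thresholds: tuple[float, ...] = (5000.0, 10000.0, 15000.0, 20000.0, 25000.0)
    max_cost: float = 250000.0
    beta: float = 0.0
    mantel_permutations: int = 10000
    mantel_alternative: str = "greater"
    priority_quantile: float = 0.05

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(t > self.max_cost for t in self.thresholds):
            raise ValueError("network thresholds must not exceed max_cost")
        if not 0 < self.priority_quantile < 1:
            raise ValueError("priority_quantile must be in (0, 1)")
        unknown = set(k.upper() for k in self.model_kinds) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kinds: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = WorldParams(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("world", {}).items()})
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        cfg = cls(world=world, **kw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d)), fh)


@dataclass
class RunReport:
    """Everything a run computed, sufficient to reproduce it."""

    seed: int
    selected_kinds: list[str]
    cv_table: pd.DataFrame
    test_metrics: dict[str, dict]
    importance: pd.DataFrame
    mantel: pd.DataFrame  # rows: LCD+roads, LCD-roads, IBR
    scale_table: pd.DataFrame
    best_threshold: float
    n_habitat_nodes: int
    n_priority_nodes: int
    priority_nodes: pd.DataFrame
    versions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "selected_kinds": list(self.selected_kinds),
            "cv_table": self.cv_table.to_dict(orient="records"),
            "test_metrics": self.test_metrics,
            "importance": self.importance.reset_index(names="variable").to_dict(orient="records"),
            "mantel": self.mantel.to_dict(orient="records"),
            "scale_table": self.scale_table.to_dict(orient="records"),
            "best_threshold": self.best_threshold,
            "n_habitat_nodes": self.n_habitat_nodes,
            "n_priority_nodes": self.n_priority_nodes,
            "priority_nodes": self.priority_nodes.to_dict(orient="records"),
            "versions": self.versions,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full analysis chain on a synthetic world.

    Stages: world simulation -> background sampling -> stratified split ->
    k-fold CV model selection -> final fits and held-out evaluation ->
    permutation importance -> committee ensemble -> resistance surface
    (with and without roads) -> LCD and IBR site distances -> three Mantel
    tests -> habitat networks across the threshold grid -> CFBC -> He-CFBC
    scale selection -> priority node extraction.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    seed = config.seed

    world: SyntheticWorld = _stage("simulate")(generate_world)(config.world, seed)
    rasters = world.env_layers
    names = [f"var{i}" for i in range(len(rasters))]

    background = _stage("background")(sample_background)(
        rasters, config.n_background, world.occurrences, derive_seed(seed, "background")
    )
    pts = PointSet.concat([world.occurrences, background])
    train, test = _stage("split")(split_train_test)(
        pts, config.train_fraction, derive_seed(seed, "split")
    )

    selected, cv_table = _stage("cv_select")(cross_validate_select)(
        config.model_kinds, train, rasters, config.cv_folds,
        derive_seed(seed, "cv"), config.model_settings,
        config.auc_gate, config.tss_gate, names,
    )
    if not selected:
        raise StageError(
            "stage 'cv_select' failed: no model passed the cross-validation gate "
            f"(AUC > {config.auc_gate}, TSS > {config.tss_gate}); pipeline halted"
        )

    fits = []
    test_metrics: dict[str, dict] = {}
    X_train = extract_covariates(rasters, train, names).to_numpy()
    X_test = extract_covariates(rasters, test, names).to_numpy()
    for kind in selected:
        fit = _stage(f"fit_{kind}")(fit_sdm)(
            kind,
            train.subset(np.nonzero(train.label == 1)[0]),
            train.subset(np.nonzero(train.label == 0)[0]),
            rasters,
            config.model_settings.get(kind),
            derive_seed(seed, f"fit_{kind}"),
            names,
        )
        fit.threshold = _max_sss_threshold(train.label, fit.predict(X_train))
        m = evaluate_predictions(test.label, fit.predict(X_test), threshold=fit.threshold)
        test_metrics[kind] = dataclasses.asdict(m)
        fits.append(fit)

    importance = _stage("importance")(importance_table)(
        fits, test, rasters, config.importance_repeats, derive_seed(seed, "importance"), names
    )

    ensemble = _stage("ensemble")(committee_ensemble)(
        fits, [f.threshold for f in fits], rasters, names
    )

    surface_roads = _stage("resistance")(compose_resistance)(
        ensemble.committee, world.roads, config.road_cost, config.anchors, config.cost_mode
    )
    surface_noroads = compose_resistance(
        ensemble.committee, world.roads.like(np.zeros(world.roads.shape)),
        config.road_cost, config.anchors, config.cost_mode,
    )

    lcd_roads = _stage("lcd")(lcd_matrix)(build_lattice(surface_roads), world.populations)
    lcd_noroads = lcd_matrix(build_lattice(surface_noroads), world.populations)
    ibr = _stage("ibr")(ibr_matrix)(surface_roads, world.populations)

    mantel_rows = []
    for label, dmat in (
        ("LCD+roads", lcd_roads),
        ("LCD-roads", lcd_noroads),
        ("IBR", ibr),
    ):
        res = _stage(f"mantel_{label}")(mantel_test)(
            world.fst, dmat, config.mantel_permutations,
            derive_seed(seed, f"mantel_{label}"), config.mantel_alternative,
        )
        mantel_rows.append(
            {"test": label, "r": res.r, "p": res.p, "n_perm": res.n_perm,
             "alternative": res.alternative}
        )
    mantel_df = pd.DataFrame(mantel_rows)

    nodes = _stage("habitat_nodes")(extract_habitat_nodes)(ensemble, surface_roads)
    per_threshold: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    cents = {}
    for thr in config.thresholds:
        graph = _stage(f"network_{thr:g}")(build_threshold_graph)(
            nodes, surface_roads, thr, config.max_cost
        )
        cent = cfbc(graph, config.beta)
        pop_nodes = assign_population_nodes(world.populations, graph)
        pop_cfbc = np.maximum(cent.scores[pop_nodes], 1e-12)  # guard log of isolated nodes
        per_threshold[thr] = (world.he, pop_cfbc)
        cents[thr] = cent

    best_thr, scale_rows = _stage("select_scale")(select_scale)(per_threshold)
    scale_df = pd.DataFrame(scale_rows)
    priority = _stage("prioritize")(prioritize_nodes)(cents[best_thr], config.priority_quantile)
    priority = priority.assign(
        x=nodes.x[priority["node"].to_numpy()], y=nodes.y[priority["node"].to_numpy()]
    )

    versions = {"connectgene": __version__, "numpy": np.__version__, "pandas": pd.__version__}
    report = RunReport(
        seed=seed,
        selected_kinds=list(selected),
        cv_table=cv_table,
        test_metrics=test_metrics,
        importance=importance,
        mantel=mantel_df,
        scale_table=scale_df,
        best_threshold=float(best_thr),
        n_habitat_nodes=len(nodes),
        n_priority_nodes=len(priority),
        priority_nodes=priority,
        versions=versions,
    )
    if out_dir is not None:
        write_report(report, out_dir, ensemble=ensemble, surface=surface_roads)
    return report


def write_report(report: RunReport, dir: str | Path, ensemble=None, surface=None) -> list[Path]:
    """Write the JSON report and CSV tables (plus rasters when provided)."""
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        files.append(path)

    payload = {"schema_version": 1, **report.to_dict()}
    _write("report.json", lambda p: p.write_text(json.dumps(payload, indent=2, default=float)))
    _write("cv_metrics.csv", lambda p: report.cv_table.to_csv(p, index=False))
    _write("importance.csv", lambda p: report.importance.to_csv(p, index_label="variable"))
    _write("mantel.csv", lambda p: report.mantel.to_csv(p, index=False))
    _write("scale_correlations.csv", lambda p: report.scale_table.to_csv(p, index=False))
    _write("priority_nodes.csv", lambda p: report.priority_nodes.to_csv(p, index=False))
    if ensemble is not None:
        _write("ensemble_committee.asc", lambda p: ensemble.committee.to_ascii(p))
        _write("suitable_mask.asc", lambda p: ensemble.suitable_mask.to_ascii(p))
    if surface is not None:
        _write("resistance.asc", lambda p: surface.cost.to_ascii(p))
    geo = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
                "properties": {"node": int(r.node), "cfbc": float(r.cfbc)},
            }
            for r in report.priority_nodes.itertuples()
        ],
    }
    _write("priority_nodes.geojson", lambda p: p.write_text(json.dumps(geo)))
    return files
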