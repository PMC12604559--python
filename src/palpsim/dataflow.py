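"""Experiment configuration, serialization, the end-to-end pipeline, and
scan-budget bookkeeping.

The pipeline chains the two stages of the palpation protocol: active GP
search for the inclusion centroid, then sliding-scan segmentation of the
boundary from that centroid at all four ray counts.  Every run is driven
by an explicit :class:`ExperimentConfig` (loadable from YAML) and explicit
seeds — there is no hidden global RNG.  Grids and tables serialize to
headered CSV, traces to JSONL, and reports to JSON, so outputs diff
cleanly and reload exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import search as search_mod
from . import sliding as sliding_mod
from .acquisition import AcquisitionConfig, Strategy
from .gp import GPConfig, ObservationSet, posterior
from .phantom import (GridSpec, PhantomSpec, Shape, StiffnessMap, make_grid,
                      make_phantom, normalize_map, standard_phantom)


# -- scan budget (A lines per B scan) ---------------------------------------

@dataclass(frozen=True)
class ScanBudget:
    """A-line bookkeeping for rotary B scanning.

    A conventional B scan assembles ``R / F`` A lines per catheter rotation
    (A-line rate R over frame rate F); the sliding mode needs a single
    A line per position, a reduction by ``alines_per_bscan - 1``.
    """

    aline_rate: float  # Hz
    frame_rate: float  # frames/s

    @property
    def alines_per_bscan(self) -> int:
        return alines_per_bscan(self.aline_rate, self.frame_rate)

    @property
    def reduction_factor(self) -> int:
        return self.alines_per_bscan - 1


def alines_per_bscan(aline_rate: float, frame_rate: float) -> int:
    """A lines per B scan, R / F; the ratio must be integral."""
    if aline_rate <= 0 or frame_rate <= 0:
        raise ValueError("rates must be positive")
    ratio = aline_rate / frame_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"A-line rate {aline_rate} is not an integer "
                         f"multiple of frame rate {frame_rate}")
    return int(round(ratio))


# -- configuration ----------------------------------------------------------

@dataclass
class SensorConfig:
    noise_sd: float = 0.0  # um on residual thickness
    d_t: float = 150.0  # um classification threshold
    preload: float = 0.1  # N, nominal; metadata for the protocol


@dataclass
class SearchConfig:
    n_iter: int = 30
    repeats: int = 1
    seed: int = 0
    checkpoints: tuple[int, ...] = search_mod.DEFAULT_CHECKPOINTS


@dataclass
class SegmentationConfig:
    n_rays_list: tuple[int, ...] = (4, 8, 12, 16)
    mode: str = "spline"
    step: float = sliding_mod.DEFAULT_STEP_MM
    delta_i_threshold: float = sliding_mod.DEFAULT_DELTA_I
    use_true_centroid: bool = False


@dataclass
class ExperimentConfig:
    shape: str = "circle"
    strategy: str = "EI"
    coarse_N: int = 5
    fine_N: int = 50
    sensor: SensorConfig = field(default_factory=SensorConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    out_dir: str = "palpsim_out"

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        if "sensor" in kw:
            kw["sensor"] = SensorConfig(**kw["sensor"])
        if "gp" in kw:
            kw["gp"] = GPConfig(**kw["gp"])
        if "acquisition" in kw:
            acq = dict(kw["acquisition"])
            if "strategy" in acq:
                acq["strategy"] = Strategy(acq["strategy"])
            kw["acquisition"] = AcquisitionConfig(**acq)
        if "search" in kw:
            sc = dict(kw["search"])
            if "checkpoints" in sc:
                sc["checkpoints"] = tuple(sc["checkpoints"])
            kw["search"] = SearchConfig(**sc)
        if "segmentation" in kw:
            seg = dict(kw["segmentation"])
            if "n_rays_list" in seg:
                seg["n_rays_list"] = tuple(seg["n_rays_list"])
            kw["segmentation"] = SegmentationConfig(**seg)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["acquisition"]["strategy"] = self.acquisition.strategy.value
        d["search"]["checkpoints"] = list(self.search.checkpoints)
        d["segmentation"]["n_rays_list"] = list(self.segmentation.n_rays_list)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def stage_rng(master_seed: int, stage: str, repeat: int = 0) -> np.random.Generator:
    """One RNG stream per (run, stage), decoupled across stages."""
    stage_id = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 stage_id, int(repeat)])
    return np.random.default_rng(ss)


# -- grid / field serialization --------------------------------------------

def save_field_csv(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write a grid-sampled field as an N x N CSV plus a JSON sidecar
    describing the lattice (rows = i / x index, columns = j / y index)."""
    path = Path(path)
    arr = np.asarray(values, dtype=float).reshape(grid.N, grid.N)
    pd.DataFrame(arr).to_csv(path, index=False)
    sidecar = {"x0": grid.x0, "y0": grid.y0, "N": grid.N,
               "dx": grid.dx, "dy": grid.dy,
               "x_min": grid.x_min, "x_max": grid.x_max,
               "y_min": grid.y_min, "y_max": grid.y_max}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_field_csv(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    path = Path(path)
    arr = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = GridSpec(**meta)
    return grid, arr.ravel()


# -- pipeline ---------------------------------------------------------------

def run_pipeline(config: ExperimentConfig) -> dict:
    """search -> centroid -> segmentation, with serialized outputs.

    Runs the active search, takes the final-iteration centroid estimate,
    segments the boundary at every configured ray count, and writes a
    consolidated JSON report plus CSV metric tables under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stiff_map = standard_phantom(config.shape)
    fine = make_grid(stiff_map.spec.workspace_extent, config.fine_N)

    search_rows = []
    traces = []
    for rep in range(config.search.repeats):
        trace = search_mod.run_search(
            stiff_map, config.strategy, acq_config=config.acquisition,
            gp_config=config.gp, n_iter=config.search.n_iter,
            seed=config.search.seed + rep, noise_sd=config.sensor.noise_sd,
            grid=fine, checkpoints=tuple(config.search.checkpoints))
        traces.append(trace)
        for N, m in trace.checkpoints.items():
            search_rows.append({"repeat": rep, "N_acq": N,
                                "N_total": N + trace.n_init, "f1": m.f1,
                                "centroid_error": m.centroid_error})
    search_table = pd.DataFrame(search_rows)
    search_table.to_csv(out / "search_metrics.csv", index=False)
    _write_trace_jsonl(out / "trace.jsonl", traces[0])

    final_N = max(traces[0].checkpoints) if traces[0].checkpoints else None
    if config.segmentation.use_true_centroid or final_N is None or \
            traces[0].checkpoints[final_N].predicted_centroid is None:
        centroid = stiff_map.true_centroid
        centroid_source = "true"
    else:
        centroid = traces[0].checkpoints[final_N].predicted_centroid
        centroid_source = f"search@N={final_N}"

    seg_rows = []
    for n_rays in config.segmentation.n_rays_list:
        bps = sliding_mod.segment(stiff_map, centroid, n_rays=n_rays,
                                  step=config.segmentation.step,
                                  delta_i_threshold=config.segmentation.delta_i_threshold)
        est = sliding_mod.reconstruct(bps, mode=config.segmentation.mode,
                                      true_area=stiff_map.analytic_area)
        seg_rows.append({"n_rays": n_rays, "mode": est.mode,
                         "estimated_area": est.area,
                         "area_error": est.area_error,
                         "precision": est.precision})
    seg_table = pd.DataFrame(seg_rows)
    seg_table.to_csv(out / "segmentation_metrics.csv", index=False)

    report = {
        "shape": config.shape,
        "strategy": str(config.strategy),
        "seed": config.search.seed,
        "centroid": list(centroid),
        "centroid_source": centroid_source,
        "true_centroid": list(stiff_map.true_centroid),
        "true_area": stiff_map.analytic_area,
        "search": search_table.to_dict(orient="records"),
        "segmentation": seg_rows,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _write_trace_jsonl(path: Path, trace) -> None:
    with open(path, "w") as fh:
        for rec in trace.records:
            fh.write(json.dumps({"t": rec.t, "x": rec.point[0],
                                 "y": rec.point[1],
                                 "thickness_um": rec.film_thickness,
                                 "class": rec.hardness_class}) + "\n")


def replay_trace(path: str | Path, grid: GridSpec,
                 gp_config: GPConfig | None = None):
    """Rebuild the GP posterior from a probe log (trace replay)."""
    X, y = [], []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            X.append([rec["x"], rec["y"]])
            y.append(float(rec["class"]))
    obs = ObservationSet(X=np.array(X), y=np.array(y))
    return posterior(obs, grid.points(), gp_config or GPConfig())


# -- fixtures ---------------------------------------------------------------

def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the three phantom configs, a 10x10 smoke phantom field, and a
    golden GP-posterior file for regression checks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for shape in ("circle", "rectangle", "horseshoe"):
        cfg = ExperimentConfig(shape=shape)
        p = out / f"{shape}.yaml"
        cfg.to_yaml(p)
        written.append(p)

    smoke_map = standard_phantom("circle")
    smoke_grid = make_grid(smoke_map.spec.workspace_extent, 10)
    values = normalize_map(smoke_map.sample(smoke_grid))
    p = out / "smoke_phantom.csv"
    save_field_csv(p, smoke_grid, values)
    written.append(p)

    # golden posterior: fixed observations on the smoke grid
    obs = ObservationSet(X=np.array([[2.0, 2.0], [5.0, 5.0], [8.0, 3.0]]),
                         y=np.array([0.0, 1.0, 0.0]))
    post = posterior(obs, smoke_grid.points(), GPConfig())
    p = out / "golden_posterior_mean.csv"
    save_field_csv(p, smoke_grid, post.mean)
    written.append(p)
    return written
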