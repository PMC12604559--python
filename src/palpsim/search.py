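"""Bayesian sequential palpation: locate the inclusion centroid actively.

The loop seeds the GP with ``n_init`` random probes, then alternates
posterior update -> acquisition -> palpation -> classification for
``n_iter`` steps on the fine grid.  Probed readings are mapped to the
binary hardness class {0, 1} before regression (the default observation
scale), so thresholding the posterior mean at 0.5 yields the predicted
inclusion mask directly; the continuous normalized-deflection scale is
available behind ``observation_scale="deflection"``.

Metrics follow the phantom benchmark: fine-grid F1 of the thresholded mask
against ground-truth membership, and the Euclidean error between the mask
centroid and the true inclusion centroid, checkpointed at
N in {5, 10, 15, 20, 25, 30} acquisition steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score as _sk_f1

from . import contact
from .acquisition import (AcquisitionConfig, Strategy, initial_design,
                          next_point)
from .gp import GPConfig, GPPosterior, ObservationSet, posterior
from .phantom import GridSpec, StiffnessMap, make_grid

DEFAULT_CHECKPOINTS = (5, 10, 15, 20, 25, 30)
MASK_CUTOFF = 0.5


class EmptyMaskError(ValueError):
    """No positive cells: the centroid is undefined."""


@dataclass
class SearchMetrics:
    f1: float
    centroid_error: float  # mm; NaN when the mask is empty
    predicted_centroid: tuple[float, float] | None
    n_positive: int


@dataclass
class ProbeRecord:
    t: int  # 0-based over the whole trace (init probes included)
    point: tuple[float, float]
    film_thickness: float  # um
    hardness_class: int


@dataclass
class SearchTrace:
    shape: str
    strategy: Strategy
    seed: int
    grid: GridSpec
    records: list[ProbeRecord]
    checkpoints: dict[int, SearchMetrics]  # keyed by acquisition step N
    observations: ObservationSet
    final_posterior: GPPosterior
    n_init: int = 5
    burn_steps: int = 0  # acquisition steps before the valid clock started


def predict_mask(post: GPPosterior, cutoff: float = MASK_CUTOFF) -> np.ndarray:
    """Binary inclusion mask: posterior mean >= cutoff, flat-index order."""
    return (post.mean >= cutoff).astype(int)


def f1_score(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Fine-grid F1 with the hard inclusion as the positive class.

    Returns 0 when no positives are predicted or present (instead of an
    undefined ratio).
    """
    pred_mask = np.asarray(pred_mask).ravel()
    truth_mask = np.asarray(truth_mask).ravel()
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("prediction and truth masks are on different grids")
    return float(_sk_f1(truth_mask, pred_mask, pos_label=1, zero_division=0))


def estimate_centroid(pred_mask: np.ndarray, grid: GridSpec) -> tuple[float, float]:
    """Arithmetic mean of the coordinates of mask-positive grid points."""
    pred_mask = np.asarray(pred_mask).ravel()
    if pred_mask.sum() == 0:
        raise EmptyMaskError("empty mask has no centroid")
    pts = grid.points()[pred_mask == 1]
    return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def _metrics(post: GPPosterior, truth_mask: np.ndarray, grid: GridSpec,
             true_centroid: tuple[float, float],
             cutoff: float = MASK_CUTOFF) -> SearchMetrics:
    mask = predict_mask(post, cutoff)
    f1 = f1_score(mask, truth_mask)
    try:
        cen = estimate_centroid(mask, grid)
        err = float(np.hypot(cen[0] - true_centroid[0], cen[1] - true_centroid[1]))
    except EmptyMaskError:
        cen, err = None, float("nan")
    return SearchMetrics(f1=f1, centroid_error=err, predicted_centroid=cen,
                         n_positive=int(mask.sum()))


def _observation_value(reading: contact.DeflectionReading, scale: str) -> float:
    if scale == "class":
        return float(reading.hardness_class)
    if scale == "deflection":
        return reading.deflection / contact.FILM_THICKNESS_UM
    raise ValueError(f"unknown observation scale {scale!r}")


def run_search(stiff_map: StiffnessMap,
               strategy: Strategy | str = Strategy.EI,
               acq_config: AcquisitionConfig | None = None,
               gp_config: GPConfig | None = None,
               n_iter: int = 30,
               seed: int = 0,
               noise_sd: float = 0.0,
               grid: GridSpec | None = None,
               checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS,
               observation_scale: str = "class",
               counting: str = "acq",
               burn_cap: int = 30) -> SearchTrace:
    """Run one active-search trace on a phantom.

    Deterministic for fixed ``(seed, configs)``: the seed drives the initial
    design and the sensor noise stream; acquisition itself is deterministic.

    ``counting`` selects the iteration clock for checkpoints and stopping:

    - ``"acq"``: count every acquisition step after the ``n_init`` prior
      samples (trace length is exactly ``n_init + n_iter``).
    - ``"valid"``: count acquisition steps only once the first probe has
      landed in the lesion (the benchmark convention: the a-priori phase
      runs until the first valid sampling point).  Burn-in acquisition
      steps before that hit are capped at ``burn_cap``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if counting not in ("acq", "valid"):
        raise ValueError("counting must be 'acq' or 'valid'")
    strategy = Strategy(strategy)
    acq_config = acq_config or AcquisitionConfig(strategy=strategy)
    if acq_config.strategy != strategy:
        acq_config = AcquisitionConfig(**{**acq_config.__dict__, "strategy": strategy})
    gp_config = gp_config or GPConfig()
    if grid is None:
        grid = make_grid(stiff_map.spec.workspace_extent, 50)
    grid_points = grid.points()
    truth_mask = stiff_map.membership_grid(grid)
    true_centroid = stiff_map.true_centroid

    ss = np.random.SeedSequence([int(seed), 0x5EA2C4])
    rng_init, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    visited_idx, init_pts = initial_design(grid, acq_config.n_init, rng_init)
    visited = list(visited_idx)
    records: list[ProbeRecord] = []
    obs = ObservationSet.empty()
    for t, pt in enumerate(init_pts):
        reading = contact.sense(stiff_map, tuple(pt), noise_sd=noise_sd,
                                rng=rng_noise)
        obs = obs.appended(pt, _observation_value(reading, observation_scale))
        records.append(ProbeRecord(t=t, point=(pt[0], pt[1]),
                                   film_thickness=reading.film_thickness,
                                   hardness_class=reading.hardness_class))

    checkpoint_metrics: dict[int, SearchMetrics] = {}
    post = posterior(obs, grid_points, gp_config)
    current = init_pts[-1]
    hit = any(r.hardness_class == 1 for r in records) if counting == "valid" \
        else True
    count = 0
    burn_steps = 0
    max_steps = n_iter if counting == "acq" else n_iter + burn_cap
    for _ in range(max_steps):
        if count >= n_iter:
            break
        idx, pt = next_point(post, obs, acq_config, gp_config,
                             visited=np.array(visited, dtype=int),
                             current=current)
        reading = contact.sense(stiff_map, tuple(pt), noise_sd=noise_sd,
                                rng=rng_noise)
        obs = obs.appended(pt, _observation_value(reading, observation_scale))
        visited.append(idx)
        current = pt
        records.append(ProbeRecord(t=len(records), point=(pt[0], pt[1]),
                                   film_thickness=reading.film_thickness,
                                   hardness_class=reading.hardness_class))
        post = posterior(obs, grid_points, gp_config)
        if hit:
            count += 1
        else:
            burn_steps += 1
            if reading.hardness_class == 1:
                hit = True  # the valid clock starts with the next step
        if hit and count in checkpoints and count > 0:
            checkpoint_metrics[count] = _metrics(post, truth_mask, grid,
                                                 true_centroid)
    # a run that never starts its valid clock reports its final state at
    # every remaining checkpoint
    for N in checkpoints:
        if N <= n_iter and N not in checkpoint_metrics:
            checkpoint_metrics[N] = _metrics(post, truth_mask, grid,
                                             true_centroid)

    return SearchTrace(shape=str(stiff_map.spec.shape.value), strategy=strategy,
                       seed=seed, grid=grid, records=records,
                       checkpoints=checkpoint_metrics, observations=obs,
                       final_posterior=post, n_init=acq_config.n_init,
                       burn_steps=burn_steps)


def benchmark(stiff_maps: dict[str, StiffnessMap],
              strategies=None,
              n_repeats: int = 20,
              n_iter: int = 30,
              seed: int = 0,
              noise_sd: float = 0.0,
              checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS,
              gp_config: GPConfig | None = None,
              n_init: int = 5,
              counting: str = "valid") -> pd.DataFrame:
    """Shape x strategy x repeat metrics table at each checkpoint.

    By default ``N`` follows the benchmark convention of counting sampling
    steps from the first probe that lands in the lesion; ``N_total`` is the
    total number of probes spent by that checkpoint (prior samples and
    burn-in included), so both countings are visible.  Empty-mask
    checkpoints carry NaN centroid error and are excluded from averages
    (the ``mask_nonempty`` column tracks coverage).
    """
    strategies = [Strategy(s) for s in (strategies or list(Strategy))]
    rows = []
    for shape, stiff_map in stiff_maps.items():
        for strat in strategies:
            acq = AcquisitionConfig(strategy=strat, n_init=n_init)
            for rep in range(n_repeats):
                trace = run_search(stiff_map, strat, acq_config=acq,
                                   gp_config=gp_config, n_iter=n_iter,
                                   seed=seed + rep, noise_sd=noise_sd,
                                   checkpoints=checkpoints, counting=counting)
                for N, m in trace.checkpoints.items():
                    rows.append({"shape": shape, "strategy": strat.value,
                                 "repeat": rep, "seed": seed + rep,
                                 "N_acq": N,
                                 "N_total": N + trace.n_init + trace.burn_steps,
                                 "f1": m.f1, "centroid_error": m.centroid_error,
                                 "mask_nonempty": m.n_positive > 0})
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean F1 / centroid error per (shape, strategy, N_acq).

    Centroid errors average over non-empty-mask repeats only; ``coverage``
    is the fraction of repeats with a non-empty mask.
    """
    if (~table["mask_nonempty"]).any():
        warnings.warn("empty-mask checkpoints excluded from centroid averages",
                      stacklevel=2)
    out = (table.groupby(["shape", "strategy", "N_acq"])
           .agg(f1=("f1", "mean"),
                centroid_error=("centroid_error", "mean"),
                coverage=("mask_nonempty", "mean"),
                N_total=("N_total", "first"))
           .reset_index())
    return out
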