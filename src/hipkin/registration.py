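"""6-DOF pose recovery by matching DRRs to measured radiographs.

The similarity between a rendered DRR and a radiographic frame is measured
either by normalized cross correlation (NCC, the default) or by the
exclusive-disjunction mismatch count between binarized silhouettes.  The
pose is found by a staged coarse-to-fine derivative-free simplex search:
early stages evaluate the metric on a decimated pixel grid with a wide
initial simplex, later stages refine at full resolution with tight
termination tolerances.  The search is deterministic; optional multi-start
perturbations are an explicit list, so a given configuration always
reproduces bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .drr import DRRImage, binarize, render
from .errors import ConstantImageError, InitializationError, ParameterError
from .geometry import Pose, ProjectionGeometry
from .volume_io import DensityVolume

logger = logging.getLogger(__name__)

_MIN_SUPPORT_PIXELS = 16


def ncc(a, b) -> float:
    """Pearson correlation of pixel values between two same-shape images."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterError("images must have the same shape")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ConstantImageError("correlation undefined for a constant image")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def xor_fitness(a, b) -> int:
    """Number of pixels where exactly one of two binary masks is set."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("masks must have the same shape")
    return int(np.logical_xor(a, b).sum())


@dataclass(frozen=True)
class Stage:
    """One resolution level of the coarse-to-fine search."""

    downsample: int = 1
    max_evaluations: int = 200
    xtol_mm: float = 0.01
    xtol_deg: float = 0.01
    simplex_step_mm: float = 0.5
    simplex_step_deg: float = 0.5

    def __post_init__(self):
        if self.downsample < 1:
            raise ParameterError("stage downsample must be >= 1")
        if self.xtol_mm <= 0 or self.xtol_deg <= 0:
            raise ParameterError("stage tolerances must be positive")


def default_stages() -> tuple[Stage, ...]:
    return (
        Stage(downsample=4, max_evaluations=150, xtol_mm=0.05, xtol_deg=0.05,
              simplex_step_mm=2.0, simplex_step_deg=2.0),
        Stage(downsample=2, max_evaluations=300, xtol_mm=0.02, xtol_deg=0.02,
              simplex_step_mm=0.5, simplex_step_deg=0.5),
        Stage(downsample=1, max_evaluations=100, xtol_mm=0.01, xtol_deg=0.01,
              simplex_step_mm=0.1, simplex_step_deg=0.1),
    )


@dataclass
class RegistrationConfig:
    """Metric choice, search stages, and multi-start perturbations.

    ``support`` selects the evaluation region for the metric: "full" (the
    default) evaluates over the whole image, "drr" only over pixels where
    the rendered DRR is nonzero.  The full-image region is fixed in the
    panel, so silhouette-size mismatch counts against a candidate pose;
    a support region that follows the moving DRR cannot see that mismatch
    and leaves the weakly constrained depth axis biased.
    ``initial_perturbations`` is a list of 6-vectors added to the initial
    pose vector for additional search starts (the unperturbed start is
    always included); the best final metric wins.
    """

    metric: str = "ncc"
    stages: tuple[Stage, ...] = field(default_factory=default_stages)
    support: str = "full"
    initial_perturbations: tuple = ()
    seed: int = 0
    step_mm: float | None = None

    def __post_init__(self):
        if self.metric not in ("ncc", "xor"):
            raise ParameterError(f"unknown metric: {self.metric!r}")
        if self.support not in ("drr", "full"):
            raise ParameterError(f"unknown support mode: {self.support!r}")
        self.stages = tuple(self.stages)
        if not self.stages:
            raise ParameterError("at least one search stage is required")


@dataclass
class StageTrace:
    stage: int
    downsample: int
    best_score: float
    pose: Pose
    n_evaluations: int


@dataclass
class RegistrationResult:
    pose: Pose
    metric_value: float
    n_evaluations: int
    converged: bool
    trace: list[StageTrace] = field(default_factory=list)


def _metric_cost(drr: DRRImage, frame_d: np.ndarray, cfg: RegistrationConfig):
    """Cost (lower = better) of a rendered DRR against a decimated frame.

    Returns None when the metric is undefined at this pose (empty or
    constant support region).
    """
    pixels = drr.pixels
    if cfg.support == "drr":
        mask = pixels > 0
        if mask.sum() < _MIN_SUPPORT_PIXELS:
            return None
        a = pixels[mask]
        b = frame_d[mask]
    else:
        a = pixels.ravel()
        b = frame_d.ravel()
    if cfg.metric == "ncc":
        try:
            return -ncc(a, b)
        except ConstantImageError:
            return None
    # xor: silhouette mismatch on the full decimated grid
    if np.ptp(pixels) == 0 or np.ptp(frame_d) == 0:
        return None
    return float(xor_fitness(binarize(pixels), binarize(frame_d)))


def _search_from(v, frame, g, x0, cfg):
    """Run all stages of the simplex search from one starting vector."""
    x = np.asarray(x0, dtype=float)
    trace: list[StageTrace] = []
    total_evals = 0
    converged = False
    for k, stage in enumerate(cfg.stages):
        frame_d = frame[::stage.downsample, ::stage.downsample]

        def cost(params):
            drr = render(v, Pose.from_vector(params), g, step=cfg.step_mm,
                         downsample=stage.downsample)
            c = _metric_cost(drr, frame_d, cfg)
            return np.inf if c is None else c

        steps = np.array([stage.simplex_step_mm] * 3
                         + [stage.simplex_step_deg] * 3)
        simplex = np.vstack([x, x + np.diag(steps)])
        xatol = min(stage.xtol_mm, stage.xtol_deg)
        res = minimize(
            cost, x, method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": stage.max_evaluations,
                "xatol": xatol,
                "fatol": 1e-12,
                "adaptive": False,
            },
        )
        x = res.x
        total_evals += res.nfev
        converged = bool(res.success)
        trace.append(StageTrace(k, stage.downsample, float(res.fun),
                                Pose.from_vector(x), res.nfev))
    return x, trace, total_evals, converged


def register_frame(
    v: DensityVolume,
    frame: np.ndarray,
    g: ProjectionGeometry,
    init: Pose,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Recover the 6-DOF pose of one bone in one radiographic frame.

    Starts the staged simplex search at ``init`` (plus any configured
    perturbed starts) and returns the best pose found.  Raises
    :class:`InitializationError` when the metric is undefined at the
    initial pose, e.g. the bone projects outside the panel.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    frame = np.asarray(frame, dtype=float)
    nv, nu = g.grid_shape
    if frame.shape != (nv, nu):
        raise ParameterError(
            f"frame shape {frame.shape} does not match geometry grid {(nv, nu)}"
        )

    d0 = cfg.stages[0].downsample
    drr0 = render(v, init, g, step=cfg.step_mm, downsample=d0)
    if _metric_cost(drr0, frame[::d0, ::d0], cfg) is None:
        raise InitializationError(
            "similarity metric undefined at the initial pose "
            "(bone outside the field of view or constant overlap region)"
        )

    starts = [init.as_vector()]
    starts += [init.as_vector() + np.asarray(p, dtype=float)
               for p in cfg.initial_perturbations]

    best = None
    for x0 in starts:
        x, trace, nev, conv = _search_from(v, frame, g, x0, cfg)
        final_cost = trace[-1].best_score
        if best is None or final_cost < best[1]:
            best = (x, final_cost, trace, nev, conv)
    x, _, trace, nev, conv = best

    pose = Pose.from_vector(x)
    final_ds = cfg.stages[-1].downsample
    drr = render(v, pose, g, step=cfg.step_mm, downsample=final_ds)
    cost = _metric_cost(drr, frame[::final_ds, ::final_ds], cfg)
    metric_value = np.nan if cost is None else (
        -cost if cfg.metric == "ncc" else cost)
    return RegistrationResult(pose=pose, metric_value=float(metric_value),
                              n_evaluations=nev, converged=conv, trace=trace)


def track_sequence(
    v: DensityVolume,
    frames: Sequence[np.ndarray],
    g: ProjectionGeometry,
    init0: Pose,
    cfg: RegistrationConfig | None = None,
) -> list[RegistrationResult]:
    """Register a frame sequence, chaining each result as the next init."""
    results: list[RegistrationResult] = []
    init = init0
    for k, frame in enumerate(frames):
        try:
            res = register_frame(v, frame, g, init, cfg)
        except Exception as exc:
            raise type(exc)(f"frame {k}: {exc}") from exc
        results.append(res)
        init = res.pose
        logger.debug("frame %d: metric=%.6f pose=%s", k, res.metric_value,
                     res.pose)
    return results
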