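"""Cluster Newton Method with the dS dividing-point modification.

The CNM solves an underdetermined inverse problem y = F(x) by evolving a
cloud ("cluster") of parameter points simultaneously.  Each iteration fits
one global affine surrogate y ≈ A w + b to the cluster (w being the working
coordinates — log-parameters by default), then moves every point by the
minimum-norm Newton step towards a slightly perturbed copy of the target,
damped by the dividing-point factor (1 − dS).  Per-point target perturbation
and the dS damping both preserve cluster diversity, so the final cluster is
an ensemble of near-solutions rather than a single optimum.

The solver is generic over the forward function; the PBPK model enters only
through a callable mapping a parameter vector to the 13 observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import BoundBox

__all__ = [
    "CNMConfig",
    "ConstraintMask",
    "Cluster",
    "ForwardFn",
    "sample_initial_cluster",
    "ssr",
    "fit_linear_map",
    "cnm_update",
    "run_cnm",
]

#: A forward evaluation returns the observable vector, or None on failure
#: (e.g. integrator breakdown); failed points are resampled by the solver.
ForwardFn = Callable[[np.ndarray], "np.ndarray | None"]


@dataclass(frozen=True)
class CNMConfig:
    """Solver settings.

    Attributes
    ----------
    n_points
        Cluster size (number of virtual samples).
    iterations
        Number of cluster updates (10 for the unconstrained stage, 15 for
        the Kp-constrained stage).
    ds
        Dividing-point ratio in [0, 1]: each point moves by (1 − dS) of its
        Newton step, so dS = 0 is the original full-step CNM and dS = 1
        freezes the cluster.
    eta
        Half-width of the multiplicative uniform perturbation applied to
        each point's private copy of the target.  By default each point
        keeps its private target for the whole run, so the cluster settles
        into an ensemble of near-solutions of slightly different problems;
        with ``perturb_once=False`` the perturbations are redrawn every
        iteration instead.
    svd_cutoff
        Relative singular-value cutoff of the pseudoinverse step.  The
        global affine surrogate carries fit noise, which tiny singular
        values amplify into large spurious moves along sloppy parameter
        directions; truncating below 2e-2 of the largest singular value
        keeps the step in the directions the surrogate actually resolves.
    seed
        Root seed; every random draw derives from it.
    sampling
        ``"log"``: sample initial points log-uniformly and take Newton steps
        in log-parameter space (multiplicative updates, positivity built
        in).  ``"linear"``: plain uniform sampling and additive steps.
    residual
        ``"relative"`` (componentwise scaled by the target) or
        ``"absolute"`` SSR.
    """

    n_points: int = 1000
    iterations: int = 10
    ds: float = 0.2
    eta: float = 0.1
    svd_cutoff: float = 2e-2
    seed: int = 0
    sampling: str = "log"
    residual: str = "relative"
    perturb_once: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ds <= 1.0:
            raise ValueError("ds must lie in [0, 1]")
        if self.sampling not in ("log", "linear"):
            raise ValueError("sampling must be 'log' or 'linear'")
        if self.residual not in ("relative", "absolute"):
            raise ValueError("residual must be 'relative' or 'absolute'")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")


@dataclass(frozen=True)
class ConstraintMask:
    """Parameter coordinates held fixed during a constrained CNM run."""

    indices: np.ndarray  # 0-based positions into the parameter vector
    values: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        val = np.asarray(self.values, dtype=float)
        if idx.shape != val.shape or idx.ndim != 1:
            raise ValueError("indices and values must be 1-d and congruent")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate fixed indices")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)

    @staticmethod
    def empty() -> "ConstraintMask":
        return ConstraintMask(np.empty(0, dtype=int), np.empty(0))

    def free_indices(self, n_params: int) -> np.ndarray:
        free = np.setdiff1d(np.arange(n_params), self.indices)
        if free.size == 0:
            raise ValueError("constraint mask leaves no free parameters")
        return free

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.array(points, dtype=float)
        out[..., self.indices] = self.values
        return out


@dataclass
class Cluster:
    """An ensemble of parameter points with their fit statistics."""

    points: np.ndarray  # (n_points, n_params)
    observables: np.ndarray  # (n_points, n_obs); rows of failed points are 0
    ssr: np.ndarray  # (n_points,); np.inf for failed points
    ok: np.ndarray  # (n_points,) bool
    iteration: int = 0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_ok(self) -> int:
        return int(self.ok.sum())

    def min_ssr(self) -> float:
        return float(self.ssr[self.ok].min()) if self.n_ok else float("inf")

    def median_ssr(self) -> float:
        return float(np.median(self.ssr[self.ok])) if self.n_ok else float("inf")


def _sample_box(rng: np.random.Generator, bounds: BoundBox, n: int,
                sampling: str) -> np.ndarray:
    if sampling == "log":
        lo, hi = np.log(bounds.lower), np.log(bounds.upper)
        return np.exp(rng.uniform(lo, hi, size=(n, len(bounds))))
    return rng.uniform(bounds.lower, bounds.upper, size=(n, len(bounds)))


def sample_initial_cluster(
    bounds: BoundBox,
    mask: ConstraintMask,
    config: CNMConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the initial cluster: free coordinates log-uniform (or uniform)
    within the bounds, fixed coordinates at their constrained values.

    Returns the raw (n_points, n_params) point matrix; forward evaluation
    is the caller's (or :func:`run_cnm`'s) job.
    """
    mask.free_indices(len(bounds))  # raises if nothing is free
    if rng is None:
        rng = np.random.default_rng(config.seed)
    points = _sample_box(rng, bounds, config.n_points, config.sampling)
    return mask.apply(points)


def ssr(calculated: np.ndarray, target: np.ndarray, mode: str = "relative") -> float:
    """Sum of squared residuals between a calculated and a target vector.

    In ``"relative"`` mode (default) each residual is scaled by its target
    entry, so percent-of-dose and μg/ml objectives contribute comparably;
    the result is invariant under joint rescaling of both vectors.
    """
    calc = np.asarray(calculated, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if calc.shape != tgt.shape:
        raise ValueError(f"length mismatch: {calc.shape} vs {tgt.shape}")
    if mode == "relative":
        if np.any(tgt == 0):
            raise ValueError("relative SSR undefined for zero target entries")
        return float(np.sum(((calc - tgt) / tgt) ** 2))
    return float(np.sum((calc - tgt) ** 2))


def _working(points: np.ndarray, config: CNMConfig) -> np.ndarray:
    return np.log(points) if config.sampling == "log" else points


def _natural(w: np.ndarray, config: CNMConfig) -> np.ndarray:
    return np.exp(w) if config.sampling == "log" else w


def _observable_scale(target: np.ndarray | None, n_obs: int,
                      config: CNMConfig) -> np.ndarray:
    """Componentwise scale of the observable space the solver works in.

    With relative residuals the linear fit and the Newton solve are done on
    y / y*, so percent-of-dose and μg/ml objectives are equilibrated the
    same way the SSR weighs them.  For a full-row-rank consistent system
    the minimum-norm step is invariant under this row scaling; it matters
    only where the singular-value truncation bites.
    """
    if config.residual == "relative" and target is not None:
        return np.asarray(target, dtype=float)
    return np.ones(n_obs)


def fit_linear_map(
    cluster: Cluster,
    free: np.ndarray,
    config: CNMConfig,
    target: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine surrogate of the forward map over the cluster.

    Fits observables against the free working coordinates of the ok points:
    y ≈ A w_free + b.  Returns ``(A, b)`` with A of shape (n_obs, n_free),
    on the raw observable scale (any internal target scaling is undone).

    Raises if fewer than ``n_free + 1`` ok points are available or the
    design is numerically rank-deficient (advice: enlarge the cluster).
    """
    okp = cluster.points[cluster.ok]
    oky = cluster.observables[cluster.ok]
    n_free = free.size
    if okp.shape[0] < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} successful points to fit the affine "
            f"surrogate, have {okp.shape[0]}; increase n_points"
        )
    W = _working(okp[:, free], config)
    design = np.column_stack([W, np.ones(W.shape[0])])
    coef, _, rank, _ = np.linalg.lstsq(design, oky, rcond=None)
    # A converged cluster loses numerical rank along directions the data no
    # longer constrain; lstsq's minimum-norm fit handles that, residuals of
    # converged points vanish, and the pseudoinverse step truncates the
    # unresolved directions — so rank loss is reported, not fatal.
    n_obs = oky.shape[1]
    if rank < min(design.shape[1], n_obs + 1):
        import warnings

        warnings.warn(
            "affine fit rank deficient below the observable dimension; the "
            "cluster may have collapsed — consider more points or larger dS",
            stacklevel=2,
        )
    A = coef[:-1].T
    b = coef[-1]
    return A, b


def cnm_update(
    cluster: Cluster,
    A: np.ndarray,
    b: np.ndarray,
    target: np.ndarray,
    config: CNMConfig,
    mask: ConstraintMask,
    bounds: BoundBox,
    rng: np.random.Generator,
    target_noise: np.ndarray | None = None,
) -> np.ndarray:
    """One cluster move: minimum-norm Newton step towards perturbed targets.

    For each successful point j a private target y*_j = y* ∘ (1 + u_j) is
    drawn (u_j uniform on [−η, η] componentwise, or taken from
    ``target_noise``), the minimum-norm solution s_j of
    A s = y*_j − y_j is computed through the singular-value pseudoinverse
    (y_j being the point's evaluated observables, which on an affine
    forward map equals the surrogate prediction A w_j + b), and the point
    moves to w_j + (1 − dS) s_j, clipped to the bounds.  With relative
    residuals the solve is row-scaled by the target so every objective
    counts as the SSR counts it.  Fixed coordinates are untouched; failed
    points are resampled within the bounds.

    Returns the new (n_points, n_params) point matrix.
    """
    free = mask.free_indices(cluster.points.shape[1])
    if not cluster.ok.any():
        raise RuntimeError("all cluster points failed; cannot update")
    scale = _observable_scale(target, target.size, config)
    pinvA = np.linalg.pinv(A / scale[:, None], rcond=config.svd_cutoff)

    W = _working(cluster.points[:, free], config)
    if target_noise is None:
        target_noise = rng.uniform(-config.eta, config.eta,
                                   size=(cluster.n_points, target.size))
    perturbed = target[None, :] * (1.0 + target_noise)
    residual = (perturbed - cluster.observables) / scale[None, :]
    steps = residual @ pinvA.T
    W_new = W + (1.0 - config.ds) * steps
    lo, hi = bounds.lower[free], bounds.upper[free]
    if config.sampling == "log":
        W_new = np.clip(W_new, np.log(lo), np.log(hi))
    else:
        W_new = np.clip(W_new, lo, hi)

    new_points = np.array(cluster.points)
    # exp(log(bound)) can land one ulp outside the box; clip once more in
    # natural space so box membership is exact
    new_points[:, free] = np.clip(_natural(W_new, config), lo, hi)
    # failed points get a fresh draw instead of a surrogate-driven move
    n_bad = int((~cluster.ok).sum())
    if n_bad:
        resampled = _sample_box(rng, bounds, n_bad, config.sampling)
        new_points[~cluster.ok] = resampled
    return mask.apply(new_points)


def _evaluate(
    forward: ForwardFn,
    points: np.ndarray,
    target: np.ndarray,
    config: CNMConfig,
    iteration: int,
) -> Cluster:
    n = points.shape[0]
    obs = np.zeros((n, target.size))
    ok = np.zeros(n, dtype=bool)
    ssr_vals = np.full(n, np.inf)
    for j in range(n):
        y = forward(points[j])
        if y is None or not np.all(np.isfinite(y)):
            continue
        obs[j] = y
        ok[j] = True
        ssr_vals[j] = ssr(y, target, config.residual)
    return Cluster(points=points, observables=obs, ssr=ssr_vals, ok=ok,
                   iteration=iteration)


def run_cnm(
    forward: ForwardFn,
    target: np.ndarray,
    bounds: BoundBox,
    mask: ConstraintMask | None = None,
    config: CNMConfig = CNMConfig(),
    initial_points: np.ndarray | None = None,
) -> list[Cluster]:
    """Run the full CNM loop and return the cluster at every iteration.

    ``history[0]`` is the evaluated initial cluster and ``history[-1]`` the
    final one; SSR values are always measured against the *unperturbed*
    target.  The run is deterministic under ``config.seed`` (serial
    evaluation order).
    """
    if mask is None:
        mask = ConstraintMask.empty()
    target = np.asarray(target, dtype=float)
    rng = np.random.default_rng(config.seed)
    if initial_points is None:
        points = sample_initial_cluster(bounds, mask, config, rng)
    else:
        points = mask.apply(initial_points)
    free = mask.free_indices(len(bounds))

    cluster = _evaluate(forward, points, target, config, iteration=0)
    history = [cluster]
    frozen_noise = (
        rng.uniform(-config.eta, config.eta, size=(config.n_points, target.size))
        if config.perturb_once else None
    )
    for it in range(1, config.iterations + 1):
        A, b = fit_linear_map(cluster, free, config)
        new_points = cnm_update(cluster, A, b, target, config, mask, bounds,
                                rng, target_noise=frozen_noise)
        cluster = _evaluate(forward, new_points, target, config, iteration=it)
        history.append(cluster)
    return history
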