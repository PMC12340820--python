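"""Metadynamics: Gaussian bias accumulation and free-energy reconstruction.

A history-dependent bias is grown by depositing Gaussian hills at the
current collective-variable (CV) value every ``stride`` integration steps:

    V_G(s, t) = sum_{t' <= t} w * exp( - sum_i (s_i - s_i(t'))^2 / (2 sigma_i^2) )

with constant height w (kJ/mol) and per-CV widths sigma_i (nm) — standard
(non-well-tempered) metadynamics. Once the landscape is filled, the negative
of the accumulated bias estimates the underlying free-energy surface; the
estimate here uses the final-time bias only, and averaging surfaces from
independent replicas supplies variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _integrators as ker
from .constants import KJ_PER_KCAL, kt
from .core import CVDefinition, DomainMap
from .toysim import IntegrationError, LangevinParams, PotentialSpec
from .umbrella import CVSeries


class PartitionError(ValueError):
    """Domain too small to split into halves."""


@dataclass
class MetaBias:
    """Deposited Gaussian hills.

    centers : (n_hills, n_cvs) nm; heights : (n_hills,) kJ/mol;
    widths : (n_hills, n_cvs) nm; times : (n_hills,) ns (deposit times).
    """

    centers: np.ndarray
    heights: np.ndarray
    widths: np.ndarray
    times: np.ndarray
    n_cvs: int

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        self.times = np.asarray(self.times, dtype=float).ravel()
        n = self.heights.shape[0]
        if n:
            if self.centers.shape != (n, self.n_cvs):
                raise ValueError("centers must be (n_hills, n_cvs)")
            if self.widths.shape != (n, self.n_cvs):
                raise ValueError("widths must be (n_hills, n_cvs)")
            if self.times.shape[0] != n:
                raise ValueError("one deposit time per hill required")
            if np.any(self.heights < 0) or np.any(self.widths <= 0):
                raise ValueError(
                    "hill heights must be >= 0 and widths > 0"
                )
            if not np.all(np.isfinite(self.centers)):
                raise ValueError("hill centers must be finite")

    def __len__(self) -> int:
        return self.heights.shape[0]

    @classmethod
    def empty(cls, n_cvs: int = 1) -> "MetaBias":
        return cls(
            centers=np.empty((0, n_cvs)),
            heights=np.empty(0),
            widths=np.empty((0, n_cvs)),
            times=np.empty(0),
            n_cvs=n_cvs,
        )

    def energy(self, s, t: Optional[float] = None):
        """Bias energy at CV point(s) ``s`` from hills deposited at times <= t."""
        return bias_energy(self, s, t)


def bias_energy(bias: MetaBias, s, t: Optional[float] = None):
    """V_G(s, t): sum of Gaussian hills deposited no later than ``t`` (kJ/mol).

    ``s`` may be a scalar (1 CV), a length-n_cvs vector, or an array of
    points with trailing dimension n_cvs.
    """
    s_arr = np.asarray(s, dtype=float)
    if bias.n_cvs == 1 and (s_arr.ndim == 0 or s_arr.shape[-1] != 1):
        s_arr = s_arr[..., None]
    if s_arr.shape[-1] != bias.n_cvs:
        raise ValueError(
            f"CV point has dimension {s_arr.shape[-1]}, bias has {bias.n_cvs}"
        )
    if len(bias) == 0:
        return np.zeros(s_arr.shape[:-1]) if s_arr.ndim > 1 else 0.0
    keep = slice(None) if t is None else bias.times <= t
    c = bias.centers[keep]
    h = bias.heights[keep]
    w = bias.widths[keep]
    # (..., 1, n_cvs) - (n_hills, n_cvs)
    d = s_arr[..., None, :] - c
    expo = -0.5 * np.sum((d / w) ** 2, axis=-1)
    v = np.sum(h * np.exp(expo), axis=-1)
    return float(v) if v.ndim == 0 else v


def run_metadynamics(
    potential: PotentialSpec,
    params: LangevinParams,
    stride: int = 1000,
    height: float = 0.25,
    width=0.08,
    x0=None,
    save_every: int = 10,
    bound: float = 1e6,
    initial_bias: Optional[MetaBias] = None,
) -> tuple[CVSeries, MetaBias]:
    """Metadynamics on an analytic potential.

    A hill of the given height (kJ/mol) and width(s) (nm) is deposited at the
    post-step CV value every ``stride`` steps, so a run of n_steps produces
    exactly floor(n_steps / stride) hills. Deterministic under the seed in
    ``params``. Defaults (stride 1000, height 0.25 kJ/mol, width 0.08 nm)
    are the deposition settings used throughout this package's experiments.
    """
    ndim = potential.ndim
    widths = np.broadcast_to(np.asarray(width, dtype=float).ravel(), (ndim,)).copy()
    if np.any(widths <= 0) or height < 0:
        raise ValueError("widths must be > 0 and height >= 0")
    rng = np.random.default_rng(params.seed)
    code, p = potential._kernel_args()
    dt = params.timestep
    a = dt / params.friction
    b = np.sqrt(2.0 * kt(params.temperature) * dt / params.friction)
    n_new = params.n_steps // stride if stride > 0 else 0
    n0 = 0 if initial_bias is None else len(initial_bias)
    if initial_bias is not None:
        if initial_bias.n_cvs != ndim:
            raise ValueError("initial bias dimensionality mismatch")
        if n0 and not (
            np.allclose(initial_bias.heights, height)
            and np.allclose(initial_bias.widths, widths)
        ):
            raise ValueError("initial bias must share the run's hill height/width")
    n_saved = params.n_steps // save_every
    times = np.arange(1, n_saved + 1) * save_every * dt / 1000.0

    hills_step = np.zeros(n0 + n_new, dtype=np.int64)
    if ndim == 1:
        hills_c = np.zeros(n0 + n_new)
        if n0:
            hills_c[:n0] = initial_bias.centers[:, 0]
        x_init = float(potential.minimum_guess() if x0 is None else x0)
        noise = rng.standard_normal(params.n_steps)
        out = np.empty(n_saved)
        status, _, nh = ker.run_1d(
            code, p, x_init, a, b, noise, 0.0, 0.0, save_every, out,
            stride, height, float(widths[0]), hills_c, hills_step, n0, bound,
        )
        if status:
            raise IntegrationError(f"coordinate diverged at step {status}")
        centers = hills_c[:nh, None]
    else:
        hills_cx = np.zeros(n0 + n_new)
        hills_cy = np.zeros(n0 + n_new)
        if n0:
            hills_cx[:n0] = initial_bias.centers[:, 0]
            hills_cy[:n0] = initial_bias.centers[:, 1]
        xy = np.asarray(potential.minimum_guess() if x0 is None else x0, dtype=float)
        noise = rng.standard_normal((params.n_steps, 2))
        out = np.empty((n_saved, 2))
        status, _, _, nh = ker.run_2d(
            code, p, xy[0], xy[1], a, b, noise, 0.0, 0.0, 0.0, 0.0,
            save_every, out, stride, height, float(widths[0]), float(widths[1]),
            hills_cx, hills_cy, hills_step, n0, bound,
        )
        if status:
            raise IntegrationError(f"coordinate diverged at step {status}")
        centers = np.stack([hills_cx[:nh], hills_cy[:nh]], axis=1)

    hill_times = hills_step[:nh] * dt / 1000.0
    if n0 and initial_bias is not None:
        hill_times[:n0] = initial_bias.times
    bias = MetaBias(
        centers=centers,
        heights=np.full(nh, height),
        widths=np.tile(widths, (nh, 1)),
        times=hill_times,
        n_cvs=ndim,
    ) if nh else MetaBias.empty(ndim)
    series = CVSeries(times=times, values=out)
    return series, bias


@dataclass
class FESGrid:
    """A gridded free-energy surface in kcal/mol, min-shifted to 0.

    axes : per-CV evenly spaced grids (nm); values : F on the grid nodes,
    shape (len(ax1),) or (len(ax1), len(ax2)).
    """

    axes: tuple
    values: np.ndarray
    n_replicas_averaged: int = 1
    empty_bias: bool = False

    def __post_init__(self):
        self.axes = tuple(np.asarray(ax, dtype=float) for ax in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(len(ax) for ax in self.axes)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )


def reconstruct_fes(bias: MetaBias, axes) -> FESGrid:
    """Free-energy surface as the negative final-time bias.

    F(s) = -V_G(s, t_final), converted to kcal/mol and shifted to min 0.
    An empty bias gives a flat surface flagged ``empty_bias``.
    """
    if isinstance(axes, (tuple, list)):
        axes = tuple(np.asarray(ax, dtype=float) for ax in axes)
    else:
        axes = (np.asarray(axes, dtype=float),)
    if len(axes) != bias.n_cvs:
        raise ValueError(f"need {bias.n_cvs} axes, got {len(axes)}")
    if len(bias) == 0:
        shape = tuple(len(ax) for ax in axes)
        return FESGrid(axes=axes, values=np.zeros(shape), empty_bias=True)
    if len(axes) == 1:
        pts = axes[0][:, None]
    else:
        g1, g2 = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.stack([g1, g2], axis=-1)
    v = bias_energy(bias, pts)
    f = -np.asarray(v) / KJ_PER_KCAL
    f = f - f.min()
    return FESGrid(axes=axes, values=f)


def average_fes(replicas: Sequence[FESGrid]) -> FESGrid:
    """Node-wise mean of min-shifted replica surfaces, re-shifted to min 0."""
    if not replicas:
        raise ValueError("need at least one replica")
    ref = replicas[0]
    acc = np.zeros_like(ref.values)
    for r in replicas:
        if len(r.axes) != len(ref.axes) or any(
            a.shape != b.shape or not np.allclose(a, b)
            for a, b in zip(r.axes, ref.axes)
        ):
            raise ValueError("replica grids do not match")
        acc += r.values - r.values.min()
    mean = acc / len(replicas)
    mean -= mean.min()
    return FESGrid(
        axes=ref.axes,
        values=mean,
        n_replicas_averaged=sum(r.n_replicas_averaged for r in replicas),
        empty_bias=all(r.empty_bias for r in replicas),
    )


def split_protomer_cvs(
    domain_map: DomainMap, protomer: str, anchor: str
) -> tuple[CVDefinition, CVDefinition, DomainMap]:
    """Split a protomer domain into contiguous halves and build two COM CVs.

    The protomer's (sorted) bead indices are partitioned at the midpoint,
    with the extra bead assigned to the first half. Returns
    ``(d1_cv, d2_cv, new_map)`` where the new DomainMap replaces the
    protomer entry by ``<protomer>_half1`` / ``<protomer>_half2`` (keeping
    all other domains), and each CV measures one half against the anchor
    domain.
    """
    idx = domain_map.indices(protomer)
    if idx.size < 2:
        raise PartitionError(f"protomer {protomer!r} has fewer than 2 beads")
    domain_map.indices(anchor)  # raises DefinitionError if unknown
    cut = (idx.size + 1) // 2  # extra bead to the first half
    half1, half2 = idx[:cut], idx[cut:]
    entries = {
        name: domain_map.indices(name)
        for name in domain_map
        if name != protomer
    }
    n1, n2 = f"{protomer}_half1", f"{protomer}_half2"
    entries[n1] = half1
    entries[n2] = half2
    new_map = DomainMap(entries)
    cv1 = CVDefinition(name="d1_COM", domain_a=n1, domain_b=anchor)
    cv2 = CVDefinition(name="d2_COM", domain_a=n2, domain_b=anchor)
    return cv1, cv2, new_map
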