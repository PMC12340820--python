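"""Synthetic data generation: Langevin toy systems with analytic ground truth.

This module stands in for the microsecond-scale all-atom MD that free-energy
and essential-dynamics estimators are normally fed. It provides

* analytic 1D/2D potentials (harmonic, double well, tilted double well) with
  closed-form energies, gradients, and basin free energies;
* an overdamped Langevin (Brownian dynamics) sampler with optional harmonic
  restraints and metadynamics bias, bitwise deterministic under a seed;
* an exact i.i.d. Gaussian sampler for harmonic window distributions (the
  clean oracle for WHAM tests);
* bead-domain complexes whose inter-domain center-of-mass distances serve as
  collective variables, plus an elastic-network covariance for them;
* multivariate-Gaussian trajectory ensembles with prescribed covariance; and
* the simulation-manifest bookkeeping of a (loop1-variant x loop2-variant x
  replica) campaign design.

Only equilibrium sampling matters for validating the estimators, so the
integrator is the overdamped Euler–Maruyama scheme rather than an
underdamped MD engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from . import _integrators as ker
from .constants import DEFAULT_TEMPERATURE, kt
from .core import DomainMap, Trajectory
from .umbrella import CVSeries, UmbrellaWindow


class IntegrationError(RuntimeError):
    """Coordinates diverged during Langevin propagation."""


class UnsupportedPotentialError(ValueError):
    """Operation requires a (locally) quadratic potential."""


_KIND_CODES = {
    "harmonic": ker.HARMONIC,
    "double_well": ker.DOUBLE_WELL,
    "tilted_double_well": ker.TILTED_DOUBLE_WELL,
    "harmonic_2d": ker.HARMONIC_2D,
    "double_well_2d": ker.DOUBLE_WELL_2D,
}


@dataclass(frozen=True)
class PotentialSpec:
    """An analytic base potential.

    kinds and parameters (energies kJ/mol, lengths nm):

    - ``harmonic``: ``kappa`` (kJ/mol/nm^2), ``center`` (default 0)
    - ``double_well``: barrier ``h`` at x=0, minima at +-``x0``;
      U = h ((x^2 - x0^2)/x0^2)^2
    - ``tilted_double_well``: double well plus linear tilt ``a``*x
      (``a`` in kJ/mol/nm)
    - ``harmonic_2d``: ``k1``, ``k2`` (+ optional ``c1``, ``c2``)
    - ``double_well_2d``: tilted double well along s1 plus harmonic ``k2``
      along s2 (separable)
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.parameters.get("kappa", 0.0) < 0:
            raise ValueError("kappa must be >= 0 (0 = flat base)")
        for key in ("h", "k1", "k2"):
            if key in self.parameters and self.parameters[key] <= 0:
                raise ValueError(f"parameter {key} must be > 0")
        if "x0" in self.parameters and self.parameters["x0"] <= 0:
            raise ValueError("x0 must be > 0")

    @property
    def ndim(self) -> int:
        return 2 if self.kind.endswith("_2d") else 1

    def _kernel_args(self):
        p = np.zeros(4)
        q = self.parameters
        if self.kind == "harmonic":
            p[0], p[1] = q["kappa"], q.get("center", 0.0)
        elif self.kind == "double_well":
            p[0], p[1] = q["h"], q["x0"]
        elif self.kind == "tilted_double_well":
            p[0], p[1], p[2] = q["h"], q["x0"], q.get("a", 0.0)
        elif self.kind == "harmonic_2d":
            p[0], p[1] = q["k1"], q["k2"]
            p[2], p[3] = q.get("c1", 0.0), q.get("c2", 0.0)
        elif self.kind == "double_well_2d":
            p[0], p[1] = q["h"], q["x0"]
            p[2], p[3] = q.get("a", 0.0), q["k2"]
        return _KIND_CODES[self.kind], p

    def energy(self, x):
        """Potential energy at coordinate(s) x, kJ/mol (vectorized)."""
        code, p = self._kernel_args()
        x = np.asarray(x, dtype=float)
        if self.ndim == 1:
            if x.ndim == 0:
                return float(ker.energy_1d(code, p, float(x)))
            return np.array([ker.energy_1d(code, p, float(v)) for v in x.ravel()]).reshape(x.shape)
        pts = x.reshape(-1, 2)
        out = np.array([ker.energy_2d(code, p, a, b) for a, b in pts])
        return float(out[0]) if x.ndim == 1 else out.reshape(x.shape[:-1])

    def gradient(self, x):
        """dU/dx at coordinate(s) x, kJ/mol/nm (vectorized)."""
        code, p = self._kernel_args()
        x = np.asarray(x, dtype=float)
        if self.ndim == 1:
            if x.ndim == 0:
                return float(ker.grad_1d(code, p, float(x)))
            return np.array([ker.grad_1d(code, p, float(v)) for v in x.ravel()]).reshape(x.shape)
        pts = x.reshape(-1, 2)
        out = np.array([ker.grad_2d(code, p, a, b) for a, b in pts])
        return out[0] if x.ndim == 1 else out.reshape(x.shape)

    def minimum_guess(self):
        """A point in (one of) the potential's wells, used as default x0."""
        q = self.parameters
        if self.kind == "harmonic":
            return q.get("center", 0.0)
        if self.kind in ("double_well", "tilted_double_well"):
            return -q["x0"]
        if self.kind == "harmonic_2d":
            return np.array([q.get("c1", 0.0), q.get("c2", 0.0)])
        return np.array([-q["x0"], 0.0])

    # convenience constructors -------------------------------------------
    @staticmethod
    def harmonic(kappa: float, center: float = 0.0) -> "PotentialSpec":
        return PotentialSpec("harmonic", {"kappa": kappa, "center": center})

    @staticmethod
    def double_well(h: float, x0: float) -> "PotentialSpec":
        return PotentialSpec("double_well", {"h": h, "x0": x0})

    @staticmethod
    def tilted_double_well(h: float, x0: float, a: float) -> "PotentialSpec":
        return PotentialSpec("tilted_double_well", {"h": h, "x0": x0, "a": a})

    @staticmethod
    def harmonic_2d(k1: float, k2: float, c1: float = 0.0, c2: float = 0.0):
        return PotentialSpec("harmonic_2d", {"k1": k1, "k2": k2, "c1": c1, "c2": c2})

    @staticmethod
    def double_well_2d(h: float, x0: float, a: float, k2: float):
        return PotentialSpec("double_well_2d", {"h": h, "x0": x0, "a": a, "k2": k2})


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Langevin parameters.

    temperature K (>= 0 to admit the zero-temperature gradient-descent
    limit), friction gamma in 1/ps, timestep in ps, n_steps, seed.
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 1e-4
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0 or self.timestep <= 0:
            raise ValueError("friction and timestep must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic restraint 1/2 k (x - center)^2 on one raw coordinate."""

    center: float
    force_constant: float
    coordinate: int = 0

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.coordinate not in (0, 1):
            raise ValueError("coordinate must be 0 or 1")


def _effective_restraint(restraints: Sequence[RestraintSpec], coordinate: int):
    """Combine harmonic restraints on one coordinate into a single one."""
    ks = [r.force_constant for r in restraints if r.coordinate == coordinate]
    if not ks or sum(ks) == 0:
        return 0.0, 0.0
    k = float(sum(ks))
    c = sum(r.force_constant * r.center for r in restraints if r.coordinate == coordinate) / k
    return c, k


def run_langevin(
    potential: PotentialSpec,
    restraints: Sequence[RestraintSpec] = (),
    params: LangevinParams = LangevinParams(),
    bias=None,
    x0=None,
    save_every: int = 1,
    bound: float = 1e6,
    source: str = "",
) -> CVSeries:
    """Overdamped Langevin sampling of an analytic potential.

    Update: x <- x - (dt/gamma) dU/dx + sqrt(2 kT dt/gamma) xi. The total
    potential is base + harmonic restraints + (static) metadynamics bias.
    Deterministic (bitwise) for a fixed seed. Raises
    :class:`IntegrationError` naming the step if |x| exceeds ``bound``.

    Returns a :class:`CVSeries` of the coordinate sampled every
    ``save_every`` steps (values shaped (n,) in 1D, (n, 2) in 2D).
    """
    rng = np.random.default_rng(params.seed)
    code, p = potential._kernel_args()
    dt = params.timestep
    a = dt / params.friction
    b = np.sqrt(2.0 * kt(params.temperature) * dt / params.friction)
    n_saved = params.n_steps // save_every
    times = np.arange(1, n_saved + 1) * save_every * dt / 1000.0  # ns

    if bias is not None and bias.n_cvs != potential.ndim:
        raise ValueError("bias dimensionality does not match the potential")
    if bias is not None and len(bias) > 0 and not (
        np.allclose(bias.heights, bias.heights[0])
        and np.allclose(bias.widths, bias.widths[0])
    ):
        raise ValueError("static bias must have uniform hill height and width")

    if potential.ndim == 1:
        c0, k0 = _effective_restraint(restraints, 0)
        x_init = float(potential.minimum_guess() if x0 is None else x0)
        if k0 > 0 and x0 is None:
            x_init = c0
        noise = rng.standard_normal(params.n_steps)
        out = np.empty(n_saved)
        if bias is not None and len(bias) > 0:
            hc = np.ascontiguousarray(bias.centers[:, 0])
            hh = float(bias.heights[0])
            hw = float(bias.widths[0, 0])
        else:
            hc, hh, hw = np.empty(0), 0.0, 1.0
        status, _, _ = ker.run_1d(
            code, p, x_init, a, b, noise, c0, k0, save_every, out,
            0, hh, hw, hc, np.empty(0, dtype=np.int64), len(hc), bound,
        )
        if status:
            raise IntegrationError(f"coordinate diverged at step {status}")
        return CVSeries(times=times, values=out, source=source)

    c0, k0 = _effective_restraint(restraints, 0)
    c1, k1 = _effective_restraint(restraints, 1)
    xy = np.asarray(potential.minimum_guess() if x0 is None else x0, dtype=float)
    noise = rng.standard_normal((params.n_steps, 2))
    out = np.empty((n_saved, 2))
    if bias is not None and len(bias) > 0:
        hcx = np.ascontiguousarray(bias.centers[:, 0])
        hcy = np.ascontiguousarray(bias.centers[:, 1])
        hh = float(bias.heights[0])
        hwx, hwy = float(bias.widths[0, 0]), float(bias.widths[0, 1])
    else:
        hcx = hcy = np.empty(0)
        hh, hwx, hwy = 0.0, 1.0, 1.0
    status, _, _, _ = ker.run_2d(
        code, p, xy[0], xy[1], a, b, noise, c0, k0, c1, k1, save_every, out,
        0, hh, hwx, hwy, hcx, hcy, np.empty(0, dtype=np.int64), len(hcx), bound,
    )
    if status:
        raise IntegrationError(f"coordinate diverged at step {status}")
    return CVSeries(times=times, values=out, source=source)


def sample_harmonic_window(
    potential: PotentialSpec,
    restraint: RestraintSpec,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> CVSeries:
    """Exact i.i.d. samples from a harmonically restrained harmonic well.

    With base U = 1/2 kappa (x - c_base)^2 and restraint
    1/2 k (x - c)^2, the Boltzmann distribution is Gaussian with mean
    (kappa c_base + k c)/(kappa + k) and variance kT/(kappa + k). This is the
    clean, closed-form sampler used to test WHAM without integrator error.
    """
    if potential.kind != "harmonic":
        raise UnsupportedPotentialError(
            f"need a harmonic base potential, got {potential.kind!r}"
        )
    kappa = potential.parameters["kappa"]
    c_base = potential.parameters.get("center", 0.0)
    k = restraint.force_constant
    if kappa + k <= 0:
        raise UnsupportedPotentialError("base and restraint cannot both be flat")
    mean = (kappa * c_base + k * restraint.center) / (kappa + k)
    sigma = np.sqrt(kt(temperature) / (kappa + k))
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sigma, size=n)
    window = UmbrellaWindow(restraint.center, k, temperature)
    return CVSeries(times=np.arange(n, dtype=float), values=values, window=window)


def basin_free_energy_difference(
    potential: PotentialSpec,
    temperature: float = DEFAULT_TEMPERATURE,
    lo: float = None,
    hi: float = None,
    split: float = None,
) -> float:
    """Analytic free-energy difference between the two basins of a 1D
    potential, Delta F = -kT ln(Z_right / Z_left) in kJ/mol, by quadrature.

    The basin boundary defaults to the barrier top (argmax of U between the
    wells); the integration range defaults to +-3*x0.
    """
    if potential.ndim != 1:
        raise UnsupportedPotentialError("1D potentials only")
    x0 = potential.parameters.get("x0", 1.0)
    lo = -3.0 * x0 if lo is None else lo
    hi = 3.0 * x0 if hi is None else hi
    if split is None:
        xs = np.linspace(-0.5 * x0, 0.5 * x0, 2001)
        split = float(xs[np.argmax(potential.energy(xs))])
    kT = kt(temperature)
    u_ref = float(min(potential.energy(np.linspace(lo, hi, 2001))))
    w = lambda x: np.exp(-(potential.energy(x) - u_ref) / kT)
    z_left, _ = quad(w, lo, split, limit=200)
    z_right, _ = quad(w, split, hi, limit=200)
    return float(-kT * np.log(z_right / z_left))


_DEFAULT_DOMAIN_NAMES = ("RBD", "CRD", "KD", "P365", "P729")


def build_bead_complex(
    n_domains: int = 5,
    beads_per_domain: int = 4,
    intra_stiffness: float = 500.0,
    inter_stiffness: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, DomainMap]:
    """A toy multi-domain bead complex with named domains.

    Domain centers sit on a circle of radius 2 nm; beads are a deterministic
    (seeded) Gaussian cloud of width 0.2 nm around each center, so all
    inter-domain COM distances are strictly positive. The stiffness
    parameters describe the implied elastic network (see
    :func:`elastic_network_covariance`). Default names follow the five-domain
    RBD/CRD/KD + two 14-3-3 protomer layout of an autoinhibited RAF-family
    complex.
    """
    if n_domains < 1 or beads_per_domain < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(_DEFAULT_DOMAIN_NAMES[:n_domains])
    names += [f"D{i}" for i in range(len(names), n_domains)]
    radius = 2.0
    frames = []
    entries = {}
    idx = 0
    for d in range(n_domains):
        theta = 2.0 * np.pi * d / max(n_domains, 2)
        center = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.1 * d])
        cloud = center + 0.2 * rng.standard_normal((beads_per_domain, 3))
        frames.append(cloud)
        entries[names[d]] = range(idx, idx + beads_per_domain)
        idx += beads_per_domain
    frame = np.concatenate(frames, axis=0)
    return frame, DomainMap(entries)


def elastic_network_covariance(
    frame: np.ndarray,
    domain_map: Optional[DomainMap] = None,
    intra_stiffness: float = 500.0,
    inter_stiffness: float = 50.0,
    cutoff: float = 2.5,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Positional covariance of an anisotropic elastic network, kT * H^+.

    Pairs within ``cutoff`` nm are connected by Hookean springs
    (``intra_stiffness`` within a domain, ``inter_stiffness`` across
    domains, kJ/mol/nm^2). The covariance is the Moore–Penrose pseudoinverse
    of the Hessian with the six rigid-body modes removed, scaled by kT.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    domain_of = np.full(n, -1)
    if domain_map is not None:
        for d, name in enumerate(domain_map):
            domain_of[domain_map.indices(name)] = d
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = frame[j] - frame[i]
            r2 = float(d @ d)
            if r2 > cutoff * cutoff or r2 == 0.0:
                continue
            k = (
                intra_stiffness
                if domain_of[i] == domain_of[j] and domain_of[i] >= 0
                else inter_stiffness
            )
            block = -k * np.outer(d, d) / r2
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    vals, vecs = np.linalg.eigh(hess)
    tol = max(vals.max(), 1.0) * 1e-9
    inv = np.where(vals > tol, 1.0 / np.where(vals > tol, vals, 1.0), 0.0)
    return kt(temperature) * (vecs * inv) @ vecs.T


def sample_gaussian_ensemble(
    mean_frame: np.ndarray,
    covariance: np.ndarray,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """I.i.d. multivariate-normal frames around a mean structure.

    ``covariance`` is (3N, 3N) symmetric positive semi-definite over the
    flattened coordinates. The ground-truth generator for validating the
    essential-dynamics estimators.
    """
    mean_frame = np.asarray(mean_frame, dtype=float)
    n_beads = mean_frame.shape[0]
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (3 * n_beads, 3 * n_beads):
        raise ValueError(f"covariance must be ({3*n_beads}, {3*n_beads})")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-10 * max(np.trace(cov), 1e-30):
        raise ValueError(f"covariance not PSD (min eigenvalue {vals.min():.3e})")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, 3 * n_beads))
    frames = mean_frame.ravel() + z @ root.T
    return Trajectory(frames=frames.reshape(n_frames, n_beads, 3))


@dataclass
class SimulationManifest:
    """Bookkeeping of a (loop1-variant x loop2-variant x replica) campaign."""

    table: pd.DataFrame

    @property
    def n_models(self) -> int:
        return int(
            self.table.drop_duplicates(["loop1_variant", "loop2_variant"]).shape[0]
        )

    @property
    def n_simulations(self) -> int:
        return int(self.table.shape[0])

    @property
    def replicas_per_model(self) -> int:
        return int(self.table.groupby(["loop1_variant", "loop2_variant"]).size().iloc[0])

    @property
    def total_time_ns(self) -> float:
        return float(self.table["run_length_ns"].sum())


def build_manifest(
    n_loop1: int = 9,
    n_loop2: int = 3,
    replicas: int = 5,
    run_length: float = 500.0,
) -> SimulationManifest:
    """Full Cartesian product of loop variants, replicated.

    The defaults encode a 9 x 3 variant library -> 27 models, 5 replicas each
    -> 135 simulations of 500 ns.
    """
    if min(n_loop1, n_loop2, replicas) < 1:
        raise ValueError("counts must be >= 1")
    rows = [
        {
            "loop1_variant": f"L1-{i}",
            "loop2_variant": f"L2-{j}",
            "replica": r,
            "run_length_ns": float(run_length),
        }
        for i in range(n_loop1)
        for j in range(n_loop2)
        for r in range(replicas)
    ]
    return SimulationManifest(table=pd.DataFrame(rows))


class SelectionError(ValueError):
    """Frame selection request exceeds the per-run frame count."""


@dataclass(frozen=True)
class FrameSelection:
    """The final ``last_n`` frame indices of each of ``n_runs`` runs."""

    n_runs: int
    per_run_frames: int
    last_n: int

    @property
    def per_run_indices(self) -> np.ndarray:
        return np.arange(self.per_run_frames - self.last_n, self.per_run_frames)

    @property
    def total(self) -> int:
        return self.n_runs * self.last_n


def select_analysis_frames(
    manifest: SimulationManifest, per_run_frames: int, last_n: int
) -> FrameSelection:
    """Select the final ``last_n`` of ``per_run_frames`` frames of every run.

    With the default campaign (135 runs) and 5000 frames per run, keeping the
    last 1000 (the equilibrated tail) yields a 135000-frame analysis library.
    """
    if last_n > per_run_frames:
        raise SelectionError(
            f"cannot select last {last_n} of {per_run_frames} frames"
        )
    return FrameSelection(
        n_runs=manifest.n_simulations,
        per_run_frames=per_run_frames,
        last_n=last_n,
    )
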