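"""Essential dynamics: trajectory PCA and mode-limited cross-correlation.

The positional covariance of a superposed trajectory,

    C_ij = < (x_i - <x_i>) (x_j - <x_j>) >,

is diagonalized as C = P Delta P^T; the leading eigenvectors (principal
modes) describe the largest-amplitude collective motions and the eigenvalues
their mean-square amplitudes (nm^2). The dynamic cross-correlation map
(DCCM) between residues i and j is computed from a truncated set of modes:

    C_ij = sum_l  (u_i^l . u_j^l) lam_l
           / sqrt( sum_l |u_i^l|^2 lam_l ) sqrt( sum_l |u_j^l|^2 lam_l )

where u_i^l is mode l's 3-vector on residue i and the sums run over the
first ``n_modes`` modes (default 10). The denominator uses the per-residue
mode-limited variances, which makes the diagonal exactly 1.

Covariances use the 1/n ensemble-average normalization; the difference from
1/(n-1) is immaterial at the frame counts this analysis is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .core import Trajectory, kabsch_superpose, _as_selection


@dataclass
class ModeDecomposition:
    """Eigendecomposition of a positional covariance matrix.

    eigenvectors : (3N, m) orthonormal columns, descending eigenvalue order;
    eigenvalues : (m,) in nm^2; mean_structure : (N, 3) or None.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mean_structure: Optional[np.ndarray] = None

    def __post_init__(self):
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvectors.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("one eigenvalue per eigenvector column required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_residues(self) -> int:
        return self.eigenvectors.shape[0] // 3


@dataclass
class CrossCorrelationMap:
    """Residue-residue normalized correlations in [-1, 1]."""

    matrix: np.ndarray
    n_modes_used: int
    degenerate_residues: tuple = ()


def compute_covariance(
    traj: Trajectory,
    selection=None,
    reference: Optional[np.ndarray] = None,
    superpose: bool = True,
) -> np.ndarray:
    """Positional covariance (3n_sel x 3n_sel, nm^2) of a trajectory.

    Frames are first rigid-body superposed onto ``reference`` (default: the
    first frame) over the selection, then the covariance of the selected
    coordinates about their average is taken with 1/n normalization.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance undefined for fewer than 2 frames")
    est = EssentialDynamics(selection=selection, superpose=superpose)
    est.fit(traj, reference=reference)
    return est.covariance_


def decompose_modes(
    covariance: np.ndarray, mean_structure: Optional[np.ndarray] = None
) -> ModeDecomposition:
    """Eigendecomposition C = P Delta P^T, descending eigenvalues.

    The sign of each eigenvector is fixed so its largest-magnitude component
    is non-negative.
    """
    c = np.asarray(covariance, dtype=float)
    nrm = np.linalg.norm(c)
    if np.linalg.norm(c - c.T) > 1e-8 * max(nrm, 1e-30):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (c + c.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign convention
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return ModeDecomposition(
        eigenvectors=vecs, eigenvalues=vals, mean_structure=mean_structure
    )


def variance_fraction(decomposition: ModeDecomposition, k: int) -> float:
    """Fraction of total fluctuation captured by the first k modes."""
    m = decomposition.n_modes
    if not 1 <= k <= m:
        raise IndexError(f"k must be in [1, {m}], got {k}")
    lam = np.clip(decomposition.eigenvalues, 0.0, None)
    total = lam.sum()
    return float(lam[:k].sum() / total) if total > 0 else 0.0


def cross_correlation_map(
    decomposition: ModeDecomposition, n_modes: int = 10
) -> CrossCorrelationMap:
    """Mode-limited dynamic cross-correlation map (DCCM).

    Residues whose mode-limited variance is zero cannot be normalized; their
    entries are set to 0 and they are reported in ``degenerate_residues``.
    """
    m = decomposition.n_modes
    if not 1 <= n_modes <= m:
        raise IndexError(f"n_modes must be in [1, {m}]")
    lam = np.clip(decomposition.eigenvalues[:n_modes], 0.0, None)
    n_res = decomposition.n_residues
    # W[i, a, l] = u_i^l[a] * sqrt(lam_l)
    w = (decomposition.eigenvectors[:, :n_modes] * np.sqrt(lam)).reshape(
        n_res, 3, n_modes
    )
    cov = np.einsum("ial,jal->ij", w, w)
    var = np.diag(cov).copy()
    degenerate = np.nonzero(var <= 0)[0]
    safe = np.where(var > 0, var, 1.0)
    corr = cov / np.sqrt(np.outer(safe, safe))
    np.fill_diagonal(corr, 1.0)
    if degenerate.size:
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return CrossCorrelationMap(
        matrix=corr,
        n_modes_used=n_modes,
        degenerate_residues=tuple(int(i) for i in degenerate),
    )


def mode_overlap(decomposition: ModeDecomposition, displacement: np.ndarray) -> np.ndarray:
    """Cosine overlap of a 3N displacement with each principal mode.

    overlap_l = |p_l . d| / ||d||, each in [0, 1]; the squared overlaps sum
    to 1 when the mode basis is complete.
    """
    d = np.asarray(displacement, dtype=float).ravel()
    if d.shape[0] != decomposition.eigenvectors.shape[0]:
        raise ValueError("displacement must have dimension 3N")
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("displacement must be nonzero")
    return np.abs(decomposition.eigenvectors.T @ d) / norm


def mode_displacement_export(
    decomposition: ModeDecomposition,
    mode: int,
    amplitude: float,
    n_frames: int = 11,
):
    """Interpolated trajectory and arrow table visualizing one mode.

    Frames move linearly from mean - amplitude*u to mean + amplitude*u, where
    u is the mode eigenvector reshaped to (N, 3). Returns
    ``(Trajectory, arrows)`` with ``arrows`` an (N, 3) per-bead displacement
    table at amplitude.
    """
    if not 0 <= mode < decomposition.n_modes:
        raise IndexError(f"mode must be in [0, {decomposition.n_modes})")
    if decomposition.mean_structure is None:
        raise ValueError("decomposition carries no mean structure")
    mean = np.asarray(decomposition.mean_structure, dtype=float)
    u = decomposition.eigenvectors[:, mode].reshape(-1, 3)
    alphas = np.linspace(-1.0, 1.0, n_frames)
    frames = mean[None, :, :] + amplitude * alphas[:, None, None] * u[None, :, :]
    traj = Trajectory(frames=frames, times=np.arange(n_frames, dtype=float))
    return traj, amplitude * u


class EssentialDynamics(BaseEstimator):
    """Trajectory PCA estimator (sklearn style).

    Parameters
    ----------
    selection : index set or None
        Beads used both for superposition fitting and for the covariance
        (e.g. all beads except flexible loops). None = all beads.
    superpose : bool, default True
        Rigid-body superpose every frame onto the reference before
        accumulating the covariance.
    n_modes : int or None
        Number of leading modes retained in ``components_``; None keeps all.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_structure_ : (n_sel, 3) average structure;
    components_ : (m, 3 n_sel) leading eigenvectors (rows);
    eigenvalues_ : (m,) nm^2, descending;
    explained_variance_ratio_ : eigenvalues / trace;
    covariance_ : (3 n_sel, 3 n_sel);
    decomposition_ : the full :class:`ModeDecomposition`.
    """

    def __init__(self, selection=None, superpose: bool = True, n_modes=None):
        self.selection = selection
        self.superpose = superpose
        self.n_modes = n_modes

    def _frames(self, X) -> np.ndarray:
        if isinstance(X, Trajectory):
            return X.frames
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:  # (n_frames, 3N)
            arr = arr.reshape(arr.shape[0], -1, 3)
        return arr

    def fit(self, X, y=None, reference: Optional[np.ndarray] = None):
        frames = self._frames(X)
        if frames.shape[0] < 2:
            raise ValueError("covariance undefined for fewer than 2 frames")
        n_beads = frames.shape[1]
        sel = (
            np.arange(n_beads)
            if self.selection is None
            else _as_selection(self.selection, n_beads)
        )
        ref = frames[0] if reference is None else np.asarray(reference, dtype=float)
        if self.superpose:
            fitted = np.empty((frames.shape[0], sel.size, 3))
            for i in range(frames.shape[0]):
                fr, _ = kabsch_superpose(frames[i], ref, sel)
                fitted[i] = fr[sel]
        else:
            fitted = frames[:, sel, :]
        flat = fitted.reshape(fitted.shape[0], -1)
        mean = flat.mean(axis=0)
        dev = flat - mean
        cov = dev.T @ dev / flat.shape[0]  # 1/n normalization
        self.mean_structure_ = mean.reshape(-1, 3)
        self.covariance_ = cov
        self.decomposition_ = decompose_modes(cov, mean_structure=self.mean_structure_)
        m = self.decomposition_.n_modes if self.n_modes is None else int(self.n_modes)
        self.components_ = self.decomposition_.eigenvectors[:, :m].T
        self.eigenvalues_ = self.decomposition_.eigenvalues[:m]
        total = np.clip(self.decomposition_.eigenvalues, 0, None).sum()
        self.explained_variance_ratio_ = (
            np.clip(self.eigenvalues_, 0, None) / total if total > 0 else self.eigenvalues_ * 0
        )
        self.selection_ = sel
        self.reference_ = ref
        return self

    def transform(self, X) -> np.ndarray:
        """Project frames onto the retained modes (mode amplitudes, nm)."""
        frames = self._frames(X)
        sel = self.selection_
        if self.superpose:
            flat = np.empty((frames.shape[0], sel.size * 3))
            for i in range(frames.shape[0]):
                fr, _ = kabsch_superpose(frames[i], self.reference_, sel)
                flat[i] = fr[sel].ravel()
        else:
            flat = frames[:, sel, :].reshape(frames.shape[0], -1)
        return (flat - self.mean_structure_.ravel()) @ self.components_.T

    def variance_fraction(self, k: int) -> float:
        return variance_fraction(self.decomposition_, k)

    def cross_correlation(self, n_modes: int = 10) -> CrossCorrelationMap:
        return cross_correlation_map(self.decomposition_, n_modes)

    def overlap(self, displacement: np.ndarray) -> np.ndarray:
        return mode_overlap(self.decomposition_, displacement)
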