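"""Geometric primitives for multi-domain bead models.

A bead model is a coarse (one bead per residue, e.g. Cα-level) representation
of a protein complex. Domains are named, disjoint sets of bead indices; the
collective variables used throughout the package are distances between domain
centers of mass. Centers of mass are unweighted centroids of the selected
beads: at Cα resolution all beads carry the same mass, so a mass table would
change nothing.

Conventions: coordinates in nm, times in ns, 0-based bead indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class DefinitionError(ValueError):
    """A domain, selection or CV definition does not resolve."""


class GeometryError(ValueError):
    """A geometric operation is ill-posed (too few / degenerate points)."""


@dataclass(frozen=True)
class CVDefinition:
    """An inter-domain center-of-mass distance collective variable."""

    name: str
    domain_a: str
    domain_b: str

    def __post_init__(self):
        if self.domain_a == self.domain_b:
            raise DefinitionError(
                f"CV {self.name!r}: domain_a and domain_b must differ "
                f"(both {self.domain_a!r})"
            )


class DomainMap:
    """Named, disjoint sets of bead indices defining domains.

    Parameters
    ----------
    entries : mapping of str -> iterable of int
        Domain name to 0-based bead indices. Sets must be non-empty and
        pairwise disjoint.
    """

    def __init__(self, entries: Mapping[str, Iterable[int]]):
        clean: dict[str, np.ndarray] = {}
        seen: set[int] = set()
        for name, idx in entries.items():
            arr = np.unique(np.asarray(list(idx), dtype=np.intp))
            if arr.size == 0:
                raise DefinitionError(f"domain {name!r} is empty")
            if arr.min() < 0:
                raise DefinitionError(f"domain {name!r} has negative indices")
            overlap = seen.intersection(arr.tolist())
            if overlap:
                raise DefinitionError(
                    f"domain {name!r} overlaps another domain at indices "
                    f"{sorted(overlap)[:5]}"
                )
            seen.update(arr.tolist())
            clean[name] = arr
        self.entries: dict[str, np.ndarray] = clean

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def indices(self, name: str) -> np.ndarray:
        try:
            return self.entries[name]
        except KeyError:
            raise DefinitionError(f"unknown domain {name!r}") from None

    @property
    def max_index(self) -> int:
        return max(int(v.max()) for v in self.entries.values())

    def validate_against(self, n_beads: int) -> None:
        if self.max_index >= n_beads:
            raise DefinitionError(
                f"domain indices reach {self.max_index} but the frame has "
                f"only {n_beads} beads"
            )

    def __repr__(self) -> str:
        body = ", ".join(f"{k}[{v.size}]" for k, v in self.entries.items())
        return f"DomainMap({body})"


@dataclass
class Trajectory:
    """An ordered sequence of frames of labeled 3D bead coordinates.

    frames : (n_frames, n_beads, 3) array, nm
    times : (n_frames,) array, ns, strictly increasing
    bead_labels : sequence of str, one per bead
    """

    frames: np.ndarray
    times: np.ndarray = None
    bead_labels: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (n_frames, n_beads, 3), got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")
        n = self.frames.shape[0]
        if self.times is None:
            self.times = np.arange(n, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n,):
            raise ValueError("times must have one entry per frame")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.bead_labels is None:
            self.bead_labels = [f"B{i}" for i in range(self.frames.shape[1])]
        if len(self.bead_labels) != self.frames.shape[1]:
            raise ValueError("one bead label per bead required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]


def _as_selection(selection, n_beads: int) -> np.ndarray:
    sel = np.asarray(list(selection), dtype=np.intp)
    if sel.size == 0:
        raise DefinitionError("empty selection")
    if sel.min() < 0 or sel.max() >= n_beads:
        raise DefinitionError(
            f"selection out of range [0, {n_beads}) : {sel.min()}..{sel.max()}"
        )
    return sel


def centroid(frame: np.ndarray, selection) -> np.ndarray:
    """Unweighted centroid of the selected beads."""
    frame = np.asarray(frame, dtype=float)
    sel = _as_selection(selection, frame.shape[0])
    return frame[sel].mean(axis=0)


def com_distance(frame: np.ndarray, domain_map: DomainMap, cv: CVDefinition) -> float:
    """Distance between the centers of mass of two domains, in nm.

    The COM of a domain is the unweighted centroid of its beads.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame coordinates must be finite")
    ca = centroid(frame, domain_map.indices(cv.domain_a))
    cb = centroid(frame, domain_map.indices(cv.domain_b))
    return float(np.linalg.norm(ca - cb))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection=None,
    return_rotation: bool = False,
):
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Finds the proper rotation + translation minimizing the RMSD of the
    selected beads (Kabsch problem, solved via
    :func:`scipy.spatial.transform.Rotation.align_vectors`) and applies it
    to *all* beads of ``mobile``.

    Returns ``(transformed, rmsd)`` where ``rmsd`` is the post-fit RMSD over
    the selection, or ``(transformed, rmsd, R)`` with the 3x3 rotation matrix
    if ``return_rotation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"shape mismatch {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    sel = np.arange(n, dtype=np.intp) if selection is None else _as_selection(selection, n)
    if sel.size < 3:
        raise GeometryError("superposition needs at least 3 selected beads")

    ref_sel = reference[sel]
    mob_sel = mobile[sel]
    ref_c = ref_sel.mean(axis=0)
    mob_c = mob_sel.mean(axis=0)
    a = ref_sel - ref_c
    b = mob_sel - mob_c
    # collinear selections leave the rotation about the common axis undefined
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise GeometryError("degenerate (collinear) selection for superposition")

    rot, _ = Rotation.align_vectors(a, b)
    transformed = rot.apply(mobile - mob_c) + ref_c
    d = transformed[sel] - ref_sel
    rmsd = float(np.sqrt((d * d).sum(axis=1).mean()))
    if return_rotation:
        return transformed, rmsd, rot.as_matrix()
    return transformed, rmsd


def radius_of_gyration(frame: np.ndarray, selection=None) -> float:
    """Root-mean-square distance of the selected beads from their centroid (nm)."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    sel = np.arange(n, dtype=np.intp) if selection is None else _as_selection(selection, n)
    pts = frame[sel]
    d = pts - pts.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection=None,
    measure_selection=None,
) -> np.ndarray:
    """Per-frame RMSD of ``measure_selection`` after fitting ``fit_selection``.

    Fitting on a folded core while measuring on flexible parts (e.g. loops)
    is the standard way to quantify local disorder without conflating it with
    global motion.

    Returns an (n_frames, 2) array of ``(time, rmsd)`` rows.
    """
    reference = np.asarray(reference, dtype=float)
    n = traj.n_beads
    msel = (
        np.arange(n, dtype=np.intp)
        if measure_selection is None
        else _as_selection(measure_selection, n)
    )
    out = np.empty((traj.n_frames, 2), dtype=float)
    for i in range(traj.n_frames):
        fitted, _ = kabsch_superpose(traj.frames[i], reference, fit_selection)
        d = fitted[msel] - reference[msel]
        out[i, 0] = traj.times[i]
        out[i, 1] = np.sqrt((d * d).sum(axis=1).mean())
    return out
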