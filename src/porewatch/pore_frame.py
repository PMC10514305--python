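"""Frame-wise rigid superposition onto the reference and pore coordinates.

Every trajectory frame is superposed (least-squares, Kabsch) onto the
crystallographic reference using all hexamer Cα atoms, so the pore normal
lies along Cartesian z.  The origin is then translated to the centroid of
the six pore-residue Cα atoms (residue 40 in the reference system), which
defines ``d_pore = 0``; ``d_pore > 0`` is the concave face (the outside of
an assembled shell) under the default orientation sign +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, TopologyError
from .trajectory_core import MoleculeTracks

# 180° rotation about x: flips z (and y), stays a proper rotation.
_FLIP_Z = np.diag([1.0, -1.0, -1.0])


@dataclass
class RigidTransform:
    """A proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), nm
    rmsd: float  # residual after superposition, nm

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise GeometryError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise GeometryError("RMSD must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class PoreFrameDefinition:
    """Reference Cα coordinates and the pore-residue origin convention.

    ``pore_ca_indices`` selects, within ``reference_ca``, the Cα atoms (one
    per protomer; six for a hexamer) whose reference-frame centroid defines
    ``d_pore = 0``.  ``orientation`` +1 keeps the reference z sign
    (increasing z = concave face); −1 flips it.
    """

    reference_ca: np.ndarray  # (K, 3) nm
    pore_ca_indices: np.ndarray  # indices into reference_ca
    pore_residue: int = 40
    orientation: int = 1

    def __post_init__(self) -> None:
        self.reference_ca = np.asarray(self.reference_ca, dtype=float)
        self.pore_ca_indices = np.asarray(self.pore_ca_indices, dtype=int)
        if not np.all(np.isfinite(self.reference_ca)):
            raise GeometryError("reference coordinates must be finite")
        if self.orientation not in (-1, 1):
            raise GeometryError("orientation sign must be +1 or -1")

    @property
    def pore_centroid(self) -> np.ndarray:
        """Reference-frame centroid of the pore-residue Cα atoms."""
        return self.reference_ca[self.pore_ca_indices].mean(axis=0)


@dataclass
class AlignedTrajectory:
    """Molecule tracks expressed in the pore frame, plus per-frame transforms.

    In the aligned frame the pore axis is z and the pore-residue Cα centroid
    sits at the origin, so ``d_pore`` is simply the z coordinate.
    """

    tracks: dict[str, MoleculeTracks]
    transforms: list[RigidTransform]
    poredef: PoreFrameDefinition
    rmsd_before: np.ndarray | None = field(default=None, repr=False)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections removed by flipping the sign of
    the smallest singular vector when the raw determinant is negative), the
    translation, and the residual RMSD.  Point sets must have equal size
    ≥ 3 and span a plane.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise GeometryError("point sets must have identical shape (n >= 3, 3)")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # Degenerate sets (collinear/coincident) leave the rotation about the
    # degenerate axis undetermined.
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def align_trajectory(
    protein_ca: np.ndarray,
    tracks: dict[str, MoleculeTracks] | list[MoleculeTracks],
    poredef: PoreFrameDefinition,
) -> AlignedTrajectory:
    """Superpose every frame onto the reference and re-express all tracks.

    ``protein_ca`` is (frames, K, 3) with the Cα atoms matched one-to-one to
    ``poredef.reference_ca``.  After superposition the pore-residue Cα
    centroid (computed in the *reference* frame) is moved to the origin and
    the orientation convention applied.
    """
    protein_ca = np.asarray(protein_ca, dtype=float)
    if isinstance(tracks, list):
        tracks = {t.species: t for t in tracks}
    if protein_ca.ndim != 3 or protein_ca.shape[1] != poredef.reference_ca.shape[0]:
        raise TopologyError(
            f"per-frame Cα count {protein_ca.shape} does not match reference "
            f"{poredef.reference_ca.shape}"
        )
    n_frames = protein_ca.shape[0]
    for tr in tracks.values():
        if tr.n_frames != n_frames:
            raise TopologyError("molecule tracks and Cα tracks disagree on frames")

    origin = poredef.pore_centroid
    flip = _FLIP_Z if poredef.orientation == -1 else np.eye(3)

    transforms: list[RigidTransform] = []
    rmsd_before = np.empty(n_frames)
    for f in range(n_frames):
        base = kabsch_superpose(protein_ca[f], poredef.reference_ca)
        rmsd_before[f] = float(
            np.sqrt(np.mean(np.sum((protein_ca[f] - poredef.reference_ca) ** 2, axis=1)))
        )
        # Compose: superpose, shift pore centroid to origin, apply orientation.
        R = flip @ base.rotation
        t = flip @ (base.translation - origin)
        transforms.append(RigidTransform(rotation=R, translation=t, rmsd=base.rmsd))

    aligned: dict[str, MoleculeTracks] = {}
    for species, tr in tracks.items():
        pos = np.empty_like(tr.positions)
        for f in range(n_frames):
            pos[f] = transforms[f].apply(tr.positions[f])
        aligned[species] = MoleculeTracks(
            species=species,
            positions=pos,
            molecule_ids=tr.molecule_ids.copy(),
            times=tr.times.copy(),
        )
    return AlignedTrajectory(
        tracks=aligned,
        transforms=transforms,
        poredef=poredef,
        rmsd_before=rmsd_before,
    )


def pore_coordinates(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map aligned positions to ``(d_pore, r)``.

    ``d_pore`` is the signed z coordinate; ``r`` the distance to the pore
    axis, ``sqrt(x² + y²)``.  Accepts a single point or any (..., 3) array.
    """
    points = np.asarray(points, dtype=float)
    d = points[..., 2]
    r = np.hypot(points[..., 0], points[..., 1])
    return d, r
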