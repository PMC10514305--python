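"""Axial occupancy profiles: N_mol(d_pore) inside an analysis cylinder.

``N_mol`` in an axial bin is the time-averaged number of molecules whose
centre of geometry lies inside the analysis cylinder (default radius 0.7 nm,
boundaries inclusive) and inside the bin.  Replicas are aggregated as the
per-bin mean with the standard error (sample SD / √n) across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .pore_frame import AlignedTrajectory, pore_coordinates
from .spatial_density import bulk_density


@dataclass
class CylinderSpec:
    """Axis-aligned analysis cylinder through the pore origin."""

    radius: float = 0.7  # nm
    z_lo: float = -3.0  # nm
    z_hi: float = 3.0  # nm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InputError("cylinder radius must be positive")
        if not self.z_lo < self.z_hi:
            raise InputError("cylinder z range must satisfy z_lo < z_hi")


class AxialProfile:
    """Per-bin time-averaged molecule counts along d_pore, with SE."""

    def __init__(
        self,
        species: str,
        bin_edges: np.ndarray,
        n_mol: np.ndarray,
        se: np.ndarray | None = None,
        n_replicas: int = 1,
        radius: float = 0.7,
    ) -> None:
        self.species = species
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.n_mol = np.asarray(n_mol, dtype=float)
        self.se = (
            np.zeros_like(self.n_mol) if se is None else np.asarray(se, dtype=float)
        )
        self.n_replicas = n_replicas
        self.radius = radius
        if np.any(self.n_mol < 0) or np.any(self.se < 0):
            raise InputError("counts and standard errors must be non-negative")
        if self.n_replicas == 1 and np.any(self.se != 0):
            raise InputError("single-replica profiles must have zero SE")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def in_cylinder(d_pore, r, spec: CylinderSpec):
    """True iff ``r ≤ radius`` and ``z_lo ≤ d_pore ≤ z_hi`` (inclusive)."""
    d_pore = np.asarray(d_pore)
    r = np.asarray(r)
    return (r <= spec.radius) & (d_pore >= spec.z_lo) & (d_pore <= spec.z_hi)


def axial_profile(
    aligned: AlignedTrajectory | np.ndarray,
    species: str,
    spec: CylinderSpec | None = None,
    bin_width: float = 0.1,
) -> AxialProfile:
    """Histogram of time-averaged molecule counts along d_pore.

    ``aligned`` may be an :class:`AlignedTrajectory` or a raw (F, M, 3)
    position array already in the pore frame.  Bins are half-open
    ``[lo, hi)`` except the last (closed); the bin grid spans exactly
    ``[z_lo, z_hi]``.
    """
    if spec is None:
        spec = CylinderSpec()
    positions = (
        aligned.tracks[species].positions
        if isinstance(aligned, AlignedTrajectory)
        else np.asarray(aligned, dtype=float)
    )
    if positions.ndim != 3 or positions.shape[0] < 1:
        raise InputError("need at least one frame of (F, M, 3) positions")
    n_frames = positions.shape[0]
    n_bins = int(round((spec.z_hi - spec.z_lo) / bin_width))
    edges = spec.z_lo + bin_width * np.arange(n_bins + 1)
    d, r = pore_coordinates(positions)
    inside = in_cylinder(d, r, spec)
    # np.histogram uses half-open bins with the last closed, matching the
    # stated convention.
    counts, _ = np.histogram(d[inside], bins=edges)
    return AxialProfile(
        species=species,
        bin_edges=edges,
        n_mol=counts / n_frames,
        n_replicas=1,
        radius=spec.radius,
    )


def aggregate_replicas(profiles: list[AxialProfile]) -> AxialProfile:
    """Mean profile with per-bin SE = sample SD / √n across replicas."""
    if not profiles:
        raise InputError("no profiles to aggregate")
    first = profiles[0]
    for p in profiles[1:]:
        if p.species != first.species or not np.allclose(p.bin_edges, first.bin_edges):
            raise InputError("profiles must share species and bin edges")
    n = len(profiles)
    stack = np.stack([p.n_mol for p in profiles])
    mean = stack.mean(axis=0)
    if n == 1:
        warnings.warn("single replica: standard errors are zero", stacklevel=2)
        se = np.zeros_like(mean)
    else:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return AxialProfile(
        species=first.species,
        bin_edges=first.bin_edges.copy(),
        n_mol=mean,
        se=se,
        n_replicas=n,
        radius=first.radius,
    )


def enrichment_profile(
    profile: AxialProfile, bulk_concentration_mM: float
) -> np.ndarray:
    """Per-bin ratio of N_mol to the uniform-bulk expectation.

    The expectation per bin is ``bulk number density × π radius² × bin
    width``; a uniform gas at the bulk concentration gives ratio ≈ 1
    everywhere.
    """
    if bulk_concentration_mM <= 0:
        raise InputError("bulk concentration must be positive")
    rho = bulk_density(bulk_concentration_mM)
    expectation = rho * np.pi * profile.radius**2 * profile.bin_width
    return profile.n_mol / expectation


def profile_table(profile: AxialProfile):
    """Tidy table (species, bin_lo, bin_hi, N_mol, SE) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "species": profile.species,
            "bin_lo_nm": profile.bin_edges[:-1],
            "bin_hi_nm": profile.bin_edges[1:],
            "n_mol": profile.n_mol,
            "se": profile.se,
        }
    )
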