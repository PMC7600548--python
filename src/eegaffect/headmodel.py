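"""Analytic single-sphere volume-conductor model.

The head is a homogeneous conducting sphere (conductivity ``sigma``, radius
``R``) with an insulating boundary.  For a current dipole with moment ``p``
at position ``b`` inside the sphere, the surface potential at an electrode
``r_e`` (|r_e| = R) has the closed form obtained by summing the Legendre
series of the boundary-corrected multipole expansion:

    V(r_e) = (1 / 4 pi sigma) * p . [ 2 d / d^3  +  (r_e + R d/|d|) / (R F) ]

with d = r_e - b, d = |d| and F = R^2 - b.r_e + R |d|.  The central-dipole
limit reduces to the textbook 3 p.r_hat / (4 pi sigma R^2).  Potentials are
returned in average reference (channel mean removed), which is also the
space in which dipole fits measure residual variance.

The electrode layout is the 64-channel Biosemi arrangement (10-20 system
extension); its standard digitization already lies on a 95 mm sphere, which
fixes the default radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RADIUS_MM = 95.0
DEFAULT_CONDUCTIVITY = 0.33  # S/m, conventional brain/scalp value

#: fraction of the sphere radius regarded as the brain compartment boundary
BRAIN_MARGIN = 0.9


def biosemi64_positions(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Channel names and unit-sphere positions of the Biosemi-64 layout.

    When ``n_channels`` < 64, an evenly spaced subset (in montage order) is
    returned, which keeps whole-head coverage for reduced-channel studies.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    ch_pos = montage.get_positions()["ch_pos"]
    names = list(ch_pos)
    pos = np.array([ch_pos[n] for n in names], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    if not 1 <= n_channels <= 64:
        raise ValueError(f"n_channels must be in [1, 64], got {n_channels}")
    if n_channels < 64:
        idx = np.round(np.linspace(0, 63, n_channels)).astype(int)
        names = [names[i] for i in idx]
        pos = pos[idx]
    return names, pos


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor with a fixed electrode montage.

    Attributes
    ----------
    sphere_radius : float
        Sphere radius in millimetres.
    channel_names : list of str
    channel_positions : ndarray, shape (n_channels, 3)
        Unit vectors; physical electrode positions are ``radius * position``.
    conductivity : float
        Homogeneous conductivity in S/m (a global scale on potentials).
    """

    sphere_radius: float = DEFAULT_RADIUS_MM
    channel_names: list[str] = field(default_factory=list)
    channel_positions: np.ndarray = field(default=None, repr=False)
    conductivity: float = DEFAULT_CONDUCTIVITY

    def __post_init__(self) -> None:
        if self.channel_positions is None:
            names, pos = biosemi64_positions()
            object.__setattr__(self, "channel_names", names)
            object.__setattr__(self, "channel_positions", pos)
        pos = np.asarray(self.channel_positions, dtype=float)
        norms = np.linalg.norm(pos, axis=1, keepdims=True)
        object.__setattr__(self, "channel_positions", pos / norms)
        if not self.channel_names:
            object.__setattr__(
                self, "channel_names", [f"CH{i:02d}" for i in range(len(pos))]
            )

    @classmethod
    def standard(cls, n_channels: int = 64, sphere_radius: float = DEFAULT_RADIUS_MM) -> "HeadModel":
        names, pos = biosemi64_positions(n_channels)
        return cls(sphere_radius=sphere_radius, channel_names=names, channel_positions=pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def electrodes_mm(self) -> np.ndarray:
        """Electrode positions in mm, shape (n_channels, 3)."""
        return self.sphere_radius * self.channel_positions

    @property
    def brain_radius(self) -> float:
        """Radius of the brain compartment (mm)."""
        return BRAIN_MARGIN * self.sphere_radius

    def contains(self, location_mm: np.ndarray, margin: float = 1.0) -> bool:
        """True when the location is strictly inside the sphere."""
        return float(np.linalg.norm(location_mm)) < margin * self.sphere_radius

    # ------------------------------------------------------------------
    def lead_field(self, location_mm: np.ndarray, moment: np.ndarray) -> np.ndarray:
        """Average-referenced potential of one dipole at every electrode.

        Parameters
        ----------
        location_mm : array-like, shape (3,)
            Dipole position in mm, strictly inside the sphere.
        moment : array-like, shape (3,)
            Dipole moment vector (arbitrary units; output is linear in it).
        """
        basis = self.lead_field_basis(location_mm)
        return basis @ np.asarray(moment, dtype=float)

    def lead_field_basis(self, location_mm: np.ndarray) -> np.ndarray:
        """The (n_channels, 3) linear map moment -> average-referenced potential."""
        b = np.atleast_2d(np.asarray(location_mm, dtype=float))
        basis = self._basis_many(b)[0]
        return basis

    def lead_field_bases(self, locations_mm: np.ndarray) -> np.ndarray:
        """Vectorized ``lead_field_basis`` for (n_locations, 3) input."""
        return self._basis_many(np.asarray(locations_mm, dtype=float))

    def _basis_many(self, b: np.ndarray) -> np.ndarray:
        R = self.sphere_radius
        radii = np.linalg.norm(b, axis=1)
        if np.any(radii >= R):
            bad = float(radii.max())
            raise ValueError(
                f"dipole location radius {bad:.1f} mm not strictly inside sphere (R={R} mm)"
            )
        r_e = self.electrodes_mm  # (C, 3)
        d = r_e[None, :, :] - b[:, None, :]  # (L, C, 3)
        dn = np.linalg.norm(d, axis=2)  # (L, C)
        F = R * R - b @ r_e.T + R * dn  # (L, C)
        # gradient of the summed series w.r.t. moment, per channel
        vec = 2.0 * d / dn[..., None] ** 3 + (r_e[None, :, :] + R * d / dn[..., None]) / (
            R * F[..., None]
        )
        vec /= 4.0 * np.pi * self.conductivity
        # average reference across channels
        vec -= vec.mean(axis=1, keepdims=True)
        return vec
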