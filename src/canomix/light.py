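"""Diffuse-light interception over a horizontally layered canopy.

Radiation is purely diffuse, following the standard-overcast-sky radiance
model, discretized into a small fixed set of sky directions (a "turtle"
sky, 16 directions by default).  The canopy is treated as a stack of
horizontal turbid-medium layers over a periodic plot: within a layer each
axis contributes optical depth k_g * area / (ground area * cos zenith),
where k_g = sin(phi_B) is the genotype's extinction coefficient, and the
flux absorbed by the layer is shared among axes in proportion to their
contribution.  Light is conserved exactly: intercepted + transmitted equals
the incident flux on the plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SkyDiscretization", "diffuse_sky", "partition_light"]


@dataclass(frozen=True)
class SkyDiscretization:
    """Discrete sky directions with diffuse-flux weights.

    ``directions`` holds (zenith, azimuth) pairs in degrees; ``weights`` the
    fraction of the diffuse incident flux arriving from each direction.
    """

    directions: np.ndarray  # (n, 2) degrees
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-12:
            raise ValueError("sky weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("sky weights must be positive")

    def __len__(self) -> int:
        return len(self.weights)


# ring layout per supported discretization: (count, zenith deg, band edges deg)
_RINGS = {
    16: [(1, 0.0, (0.0, 7.5)), (5, 15.0, (7.5, 30.0)),
         (5, 45.0, (30.0, 60.0)), (5, 75.0, (60.0, 90.0))],
    46: [(1, 0.0, (0.0, 9.0)), (5, 18.0, (9.0, 27.0)),
         (10, 36.0, (27.0, 45.0)), (15, 54.0, (45.0, 63.0)),
         (15, 72.0, (63.0, 90.0))],
}


def diffuse_sky(n_directions: int = 16) -> SkyDiscretization:
    """Standard-overcast turtle sky with 16 (default) or 46 directions.

    Each direction's weight is the overcast radiance (1 + 2 cos z)/3 times
    cos z times the solid angle of its sky sector, normalized to sum to 1 —
    i.e. the fraction of the diffuse flux on a horizontal surface arriving
    from that sector.
    """
    if n_directions not in _RINGS:
        raise ValueError(
            f"unsupported n_directions {n_directions}; choose from {sorted(_RINGS)}"
        )
    dirs: list[tuple[float, float]] = []
    weights: list[float] = []
    for count, zen, (lo, hi) in _RINGS[n_directions]:
        band_omega = 2.0 * np.pi * (np.cos(np.radians(lo)) - np.cos(np.radians(hi)))
        cz = np.cos(np.radians(zen))
        w = (1.0 + 2.0 * cz) / 3.0 * cz * band_omega / count
        for i in range(count):
            # stagger azimuths between rings to avoid aligned directions
            az = (360.0 * i / count + 36.0 * len(dirs)) % 360.0 if count > 1 else 0.0
            dirs.append((zen, az))
            weights.append(w)
    w_arr = np.array(weights)
    w_arr /= w_arr.sum()
    return SkyDiscretization(directions=np.array(dirs), weights=w_arr)


def partition_light(
    profiles: np.ndarray,
    extinction: np.ndarray,
    sky: SkyDiscretization,
    incident: float,
    ground_area: float,
) -> tuple[np.ndarray, float]:
    """Share one day's diffuse PAR among axes of a layered canopy.

    Parameters
    ----------
    profiles
        (n_axes, n_layers) green areas in cm2; layer 0 is the lowest.
    extinction
        per-axis extinction coefficient k_g (sin of the blade insertion
        angle of the axis' genotype).
    sky
        diffuse sky discretization.
    incident
        incident PAR above the canopy, mol m-2 d-1.
    ground_area
        plot ground area, m2.

    Returns
    -------
    (intercepted, transmitted)
        per-axis intercepted PAR (mol d-1) and PAR transmitted to the
        ground (mol d-1); their sum equals incident * ground_area.
    """
    profiles = np.asarray(profiles, dtype=float)
    extinction = np.asarray(extinction, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] != extinction.shape[0]:
        raise ValueError("profiles and extinction must agree on the axis count")
    if incident < 0 or ground_area <= 0:
        raise ValueError("incident must be >= 0 and ground_area > 0")
    if np.any(profiles < 0):
        raise ValueError("green areas must be >= 0")

    n_axes, n_layers = profiles.shape
    total_flux = incident * ground_area  # mol d-1 onto the plot
    if n_axes == 0 or total_flux == 0.0 or profiles.sum() == 0.0:
        return np.zeros(n_axes), float(total_flux)

    ground_cm2 = ground_area * 1e4
    ka = extinction[:, None] * profiles  # (n_axes, n_layers)
    col = ka.sum(axis=0)  # per-layer k-weighted area, cm2
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(col > 0, ka / col, 0.0)  # per-layer axis shares

    cosz = np.cos(np.radians(sky.directions[:, 0]))  # (n_dirs,)
    # vertical optical depth per layer, scaled by the slant path per direction
    depth = col[None, :] / (ground_cm2 * cosz[:, None])  # (n_dirs, n_layers)
    # process top-down: cumulative depth of the layers above each layer
    above = np.cumsum(depth[:, ::-1], axis=1)[:, ::-1] - depth
    absorbed_frac = np.exp(-above) * (1.0 - np.exp(-depth))  # per layer
    flux_per_dir = total_flux * sky.weights  # (n_dirs,)
    layer_flux = (flux_per_dir[:, None] * absorbed_frac).sum(axis=0)  # (n_layers,)
    intercepted = share @ layer_flux
    transmitted = float(np.sum(flux_per_dir * np.exp(-depth.sum(axis=1))))
    return intercepted, transmitted
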