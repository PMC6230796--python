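"""Inverse current source density (delta-source iCSD) and layer assignment.

Laminar LFPs recorded on a linear probe (32 contacts, 50 um spacing) are
converted to a current source density profile with the delta-source inverse
method: current is assumed to originate from infinitesimally thin disks of
radius R (default 125 um, i.e. a 250 um diameter) centred on each contact
plane, in a homogeneous, isotropic medium of conductivity sigma (default
0.3 S/m).  The potential at contact j produced by a unit planar source at
contact i is then

    P[j, i] = (h / (2 sigma)) * (sqrt((z_j - z_i)^2 + R^2) - |z_j - z_i|)

with h the inter-contact spacing (each disk stands for the current in a
slab of thickness h).  Collecting these solutions in the forward matrix P,
the CSD estimate is the matrix inverse applied to the recorded potentials:
C_hat = P^-1 Phi, column by column over time.

The most prominent CSD feature in auditory cortex is the polarity reversal
at the layer 1 - layer 2/3 border; its depth anchors the laminar
coordinate.  Layers are assigned from depth below that border using
published cortical-thickness measurements: [0, 225) um -> layer 2/3,
[225, 425) -> layer 4, [425, 675) -> layer 5, >= 675 -> layer 6 (half-open
intervals; negative depths are layer 1 / excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIGMA_S_PER_M = 0.3
DISK_DIAMETER_UM = 250.0
LAYER_BOUNDS_UM = ((0.0, 225.0, "2/3"), (225.0, 425.0, "4"),
                   (425.0, 675.0, "5"), (675.0, np.inf, "6"))

__all__ = [
    "LaminarLFP",
    "ForwardModel",
    "CSDProfile",
    "build_forward_matrix",
    "estimate_csd",
    "find_reversal_depth",
    "assign_layer",
]


@dataclass(frozen=True)
class LaminarLFP:
    """Channels-by-time potential matrix (uV), superficial channel first."""

    phi: np.ndarray  # (n_channels, n_samples), uV
    depths_um: np.ndarray  # (n_channels,), increasing
    fs: float | None = None

    def __post_init__(self) -> None:
        phi = np.atleast_2d(np.asarray(self.phi, float))
        depths = np.asarray(self.depths_um, float)
        if phi.shape[0] != len(depths):
            raise ValueError("channel count mismatch between phi and depths")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing (superficial first)")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "depths_um", depths)

    @property
    def contact_spacing_um(self) -> float:
        return float(np.diff(self.depths_um)[0])


@dataclass(frozen=True)
class ForwardModel:
    """Electrostatic forward solutions P for the delta-source geometry."""

    P: np.ndarray  # (n_channels, n_channels)
    depths_um: np.ndarray
    sigma: float = SIGMA_S_PER_M
    disk_diameter_um: float = DISK_DIAMETER_UM


@dataclass(frozen=True)
class CSDProfile:
    """Estimated CSD (channels x time) plus optional laminar anchoring."""

    c_hat: np.ndarray
    depths_um: np.ndarray
    fs: float | None = None
    reversal_depth_um: float | None = None


def build_forward_matrix(
    depths_um: np.ndarray,
    sigma: float = SIGMA_S_PER_M,
    disk_diameter_um: float = DISK_DIAMETER_UM,
) -> ForwardModel:
    """Forward matrix of the delta-source iCSD method.

    Requires at least two uniformly spaced contact depths; ``sigma`` is the
    extracellular conductivity in S/m and ``disk_diameter_um`` the assumed
    diameter of the planar current disks.
    """
    depths = np.asarray(depths_um, float)
    if len(depths) < 2:
        raise ValueError("need at least two contacts")
    spacings = np.diff(depths)
    if np.any(spacings <= 0) or not np.allclose(spacings, spacings[0], rtol=1e-6):
        raise ValueError("contact depths must be uniformly spaced")
    if sigma <= 0 or disk_diameter_um <= 0:
        raise ValueError("sigma and disk diameter must be positive")
    h = spacings[0] * 1e-6  # m
    radius = disk_diameter_um / 2.0 * 1e-6  # m
    z = depths * 1e-6
    dz = np.abs(z[:, None] - z[None, :])
    P = (h / (2.0 * sigma)) * (np.sqrt(dz**2 + radius**2) - dz)
    return ForwardModel(P=P, depths_um=depths, sigma=sigma,
                        disk_diameter_um=disk_diameter_um)


def estimate_csd(lfp: LaminarLFP, fm: ForwardModel) -> CSDProfile:
    """C_hat = P^-1 Phi, applied column-by-column over time."""
    if lfp.phi.shape[0] != fm.P.shape[0]:
        raise ValueError("channel count does not match the forward model")
    cond = np.linalg.cond(fm.P)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("forward matrix is singular or ill-conditioned")
    c_hat = np.linalg.solve(fm.P, lfp.phi)
    return CSDProfile(c_hat=c_hat, depths_um=lfp.depths_um, fs=lfp.fs)


def find_reversal_depth(
    csd: CSDProfile,
    window: slice | np.ndarray | None = None,
    noise_floor: float | None = None,
    baseline_window: slice | None = None,
) -> float:
    """Depth of the superficial polarity reversal (layer 1 - 2/3 border).

    The per-channel CSD is averaged over an early-response time ``window``
    (default: all samples).  Scanning from the most superficial channel
    down, the first adjacent pair whose mean CSD changes sign with both
    magnitudes above ``noise_floor`` marks the border; the midpoint of the
    two contact depths is returned.  ``noise_floor`` defaults to twice the
    SD of the CSD in ``baseline_window`` (pre-stimulus), or 0 if no baseline
    is given.

    Raises
    ------
    ValueError
        If no qualifying sign change exists.
    """
    window = slice(None) if window is None else window
    profile = csd.c_hat[:, window].mean(axis=1)
    if noise_floor is None:
        if baseline_window is not None:
            noise_floor = 2.0 * float(np.std(csd.c_hat[:, baseline_window]))
        else:
            noise_floor = 0.0
    for i in range(len(profile) - 1):
        a, b = profile[i], profile[i + 1]
        if np.sign(a) != np.sign(b) and a != 0 and b != 0 \
                and abs(a) > noise_floor and abs(b) > noise_floor:
            return float((csd.depths_um[i] + csd.depths_um[i + 1]) / 2.0)
    raise ValueError("no reversal found: no qualifying sign change in the "
                     "early-window CSD profile")


def assign_layer(depth_below_border_um: float) -> str:
    """Cortical layer for a depth below the layer 1 - 2/3 border (um).

    Half-open intervals: [0, 225) -> '2/3', [225, 425) -> '4',
    [425, 675) -> '5', [675, inf) -> '6'; negative depths -> '1'.
    """
    d = float(depth_below_border_um)
    if not np.isfinite(d):
        raise ValueError("depth must be finite")
    if d < 0:
        return "1"
    for lo, hi, label in LAYER_BOUNDS_UM:
        if lo <= d < hi:
            return label
    raise AssertionError("unreachable: layer intervals partition [0, inf)")
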