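"""Structural analysis of solute-water snapshots.

Spherical droplet cutting, site-site radial distribution functions g(r)
and running coordination numbers n(r) = 4 pi rho \\int_0^r g(s) s^2 ds.
The O...Hw RDF of a carbonyl acceptor peaking near 1.8 A with a running
coordination of ~2 at the first minimum is the structural signature of a
two-water hydrogen-bond shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Snapshot",
    "RDFCurve",
    "RCNCurve",
    "spherical_cut",
    "radial_distribution",
    "running_coordination_number",
    "first_minimum",
]

#: Default histogram bin width (Angstrom) and range (Angstrom).
DEFAULT_BIN_WIDTH = 0.05
DEFAULT_R_MAX = 8.0


@dataclass
class Snapshot:
    """One solute-solvent configuration.

    solute_labels / solute_coords : per-site labels and (n, 3) Angstrom.
    solvent_coords : (n_waters, 3, 3) Angstrom, rigid O/H/H triplets.
    box : optional cubic periodic cell edge lengths (3,), Angstrom; None
    for droplets.
    """

    solute_labels: list[str]
    solute_coords: np.ndarray
    solvent_coords: np.ndarray
    solvent_labels: tuple[str, str, str] = ("OW", "HW1", "HW2")
    box: np.ndarray | None = None
    snapshot_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.solute_coords = np.asarray(self.solute_coords, dtype=float).reshape(-1, 3)
        self.solvent_coords = np.asarray(self.solvent_coords, dtype=float)
        if self.solvent_coords.size == 0:
            self.solvent_coords = np.zeros((0, 3, 3))
        if self.solvent_coords.ndim != 3 or self.solvent_coords.shape[1:] != (3, 3):
            raise ValueError("solvent molecules must be intact 3-site triplets")
        if not (
            np.all(np.isfinite(self.solute_coords))
            and np.all(np.isfinite(self.solvent_coords))
        ):
            raise ValueError("non-finite coordinates in snapshot")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_waters(self) -> int:
        return self.solvent_coords.shape[0]

    def all_labels(self) -> list[str]:
        return list(self.solute_labels) + list(self.solvent_labels) * self.n_waters

    def all_coords(self) -> np.ndarray:
        if self.n_waters == 0:
            return self.solute_coords.copy()
        return np.vstack([self.solute_coords, self.solvent_coords.reshape(-1, 3)])

    def select(self, selector: str) -> np.ndarray:
        """Coordinates of all sites whose label matches *selector*.

        A label matches if it equals the selector or starts with it,
        case-insensitively: ``"O2"`` picks the solute carbonyl oxygen,
        ``"Hw"`` picks both water hydrogens (HW1, HW2).
        """
        sel = selector.lower()
        labels = self.all_labels()
        coords = self.all_coords()
        mask = np.array([lab.lower().startswith(sel) for lab in labels])
        if not mask.any():
            raise ValueError(f"selector {selector!r} matches no sites")
        return coords[mask]


@dataclass
class RDFCurve:
    """Radial distribution function on a uniform r grid."""

    r_centers: np.ndarray
    g: np.ndarray
    bulk_density: float
    pair_label: tuple[str, str]

    def __post_init__(self):
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.r_centers[1] - self.r_centers[0])


@dataclass
class RCNCurve:
    """Running coordination number n(r) (cumulative partner count)."""

    r_centers: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any(np.diff(self.n) < -1e-12):
            raise ValueError("running coordination number must be nondecreasing")


def spherical_cut(frame: Snapshot, center: np.ndarray, radius: float) -> Snapshot:
    """Cut a droplet of given radius (Angstrom) around *center*.

    Whole solvent molecules are kept iff their oxygen lies within the
    radius, so no water is ever split (split waters would break the
    per-molecule charge constraints downstream).  The solute is always
    retained and the periodic cell is dropped.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    if frame.n_waters:
        o_dist = np.linalg.norm(frame.solvent_coords[:, 0, :] - center, axis=1)
        keep = o_dist <= radius
        kept = frame.solvent_coords[keep]
    else:
        kept = frame.solvent_coords
    if kept.shape[0] == 0 and frame.n_waters > 0:
        warnings.warn("spherical cut removed every solvent molecule", stacklevel=2)
    return Snapshot(
        solute_labels=list(frame.solute_labels),
        solute_coords=frame.solute_coords.copy(),
        solvent_coords=kept.copy(),
        solvent_labels=frame.solvent_labels,
        box=None,
        snapshot_id=frame.snapshot_id,
        metadata=dict(frame.metadata),
    )


def _pair_distances(a: np.ndarray, b: np.ndarray, r_max: float,
                    box: np.ndarray | None) -> np.ndarray:
    """All A-B distances below r_max, excluding coincident (self) pairs."""
    if box is not None:
        d = a[:, None, :] - b[None, :, :]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=-1).ravel()
    else:
        tree = cKDTree(b)
        pairs = tree.query_ball_point(a, r_max)
        r = np.concatenate(
            [np.linalg.norm(b[idx] - a[i], axis=1) for i, idx in enumerate(pairs) if idx]
            or [np.empty(0)]
        )
    return r[(r > 1e-9) & (r < r_max)]


def radial_distribution(
    snapshots: list[Snapshot],
    site_a: str,
    site_b: str,
    r_max: float = DEFAULT_R_MAX,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bulk_density: float | None = None,
) -> RDFCurve:
    """Snapshot-averaged radial distribution of B sites around A sites.

    g(r) = <counts(r)> / (N_a * 4 pi r^2 dr * rho_b).  The bulk B density
    rho_b is, in order of preference: the explicit ``bulk_density``
    argument; N_b / V_box when snapshots carry a periodic cell (distances
    then use the minimum image); otherwise the mean B density measured
    within r_max of the A sites — the appropriate normalisation for a
    finite droplet, where no true bulk exists.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(centers.size)
    n_a_total = 0
    local_counts = 0.0
    n_b_total = 0

    for snap in snapshots:
        a = snap.select(site_a)
        b = snap.select(site_b)
        if snap.box is not None and r_max > snap.box.min() / 2:
            warnings.warn("r_max exceeds half the box; minimum image truncated",
                          stacklevel=2)
        r = _pair_distances(a, b, edges[-1], snap.box)
        hist += np.histogram(r, bins=edges)[0]
        n_a_total += len(a)
        n_b_total += len(b)
        local_counts += r.size

    if bulk_density is None:
        boxes = [s.box for s in snapshots]
        if all(bx is not None for bx in boxes):
            vols = [float(np.prod(bx)) for bx in boxes]
            bulk_density = n_b_total / sum(vols)
        else:
            # droplet: mean B density in the r_max ball around each A site
            bulk_density = local_counts / (n_a_total * 4.0 / 3.0 * np.pi * r_max**3)
    if bulk_density <= 0:
        raise ValueError("bulk density must be positive")

    shell = 4.0 * np.pi * centers**2 * bin_width
    g = hist / (n_a_total * shell * bulk_density)
    return RDFCurve(r_centers=centers, g=g, bulk_density=float(bulk_density),
                    pair_label=(site_a, site_b))


def running_coordination_number(rdf: RDFCurve) -> RCNCurve:
    """Integrate the RDF: n(r) = 4 pi rho_b \\int_0^r g(s) s^2 ds.

    Trapezoidal accumulation on the stored grid, anchored at n(0) = 0.
    """
    r = np.concatenate([[0.0], rdf.r_centers])
    integrand = 4.0 * np.pi * rdf.bulk_density * np.concatenate([[0.0], rdf.g]) * r**2
    n = np.concatenate([[0.0], np.cumsum(
        0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r)
    )])
    return RCNCurve(r_centers=rdf.r_centers, n=n[1:])


def first_minimum(rdf: RDFCurve, smooth_window: int = 5) -> float:
    """Position (Angstrom) of the first local minimum after the first peak.

    g(r) is smoothed with a flat window (default 5 points) before the
    search so that single-bin noise does not masquerade as structure.
    """
    g = rdf.g
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    imax = int(np.argmax(g))
    for i in range(imax + 1, g.size - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            return float(rdf.r_centers[i])
    raise ValueError("no local minimum after the first peak")
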