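"""Constrained fluctuating-charge(-and-dipole) polarizable embedding.

The MM solvent sites carry variational charges (FQ) and optionally induced
point dipoles (FQFmu).  Given per-site electronegativities ``chi``, chemical
hardnesses ``eta`` and isotropic polarizabilities ``alpha``, plus the
external potential ``V`` and field ``E`` imprinted by the solute, the
charges and dipoles minimise the quadratic energy functional

    U(q, mu) = 1/2 q^T Tqq q + q^T Tqmu mu + 1/2 mu^T Tmumu mu
               + (chi + V)^T q - E . mu

subject to charge-conservation constraints: the net charge of every MM
molecule is fixed (FQ, FQFMU), or only the total system charge is fixed
so that charge may flow between molecules (FQFMU_CT).  The stationarity
conditions form a symmetric saddle-point linear system in (q, lambda, mu)
whose right-hand side is (-chi - V, Qtot, +E); the FQ system is obtained
by deleting the dipole rows and columns.

Everything here works in Hartree atomic units; site positions are stored
in Angstrom and converted on kernel assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.spatial

from .units import angstrom_to_bohr

__all__ = [
    "PolarizableSite",
    "MMTopology",
    "ForceFieldVariant",
    "ExternalSource",
    "KernelMatrices",
    "LinearProblem",
    "EmbeddingSolution",
    "DegenerateGeometryError",
    "ParameterError",
    "build_kernels",
    "assemble_system",
    "solve_embedding",
    "interaction_energy",
    "solute_point_source",
    "water_topology",
    "PARAMETER_SETS",
    "template_parameter_set",
]

#: Minimum allowed separation between MM sites (Angstrom). Closer pairs are
#: rejected as degenerate rather than regularised.
MIN_SITE_SEPARATION = 0.1

#: Minimum allowed solute-to-MM-site distance (Angstrom).
MIN_SOLUTE_SEPARATION = 0.5

#: Residual tolerance (a.u.) above which a solve is declared degenerate.
SOLVER_TOLERANCE = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised for coincident or near-coincident interaction sites."""


class ParameterError(ValueError):
    """Raised for force-field parameters inconsistent with the variant."""


class ForceFieldVariant(Enum):
    """Flavour of the polarizable solvent model.

    FQ       -- fluctuating charges only; per-molecule charge constraints.
    FQFMU    -- charges plus induced dipoles; per-molecule constraints.
    FQFMU_CT -- charges plus dipoles; a single total-charge constraint, so
                charge may transfer between solvent molecules.
    """

    FQ = "FQ"
    FQFMU = "FQFmu"
    FQFMU_CT = "FQFmuCT"

    @property
    def has_dipoles(self) -> bool:
        return self is not ForceFieldVariant.FQ

    @property
    def charge_transfer(self) -> bool:
        return self is ForceFieldVariant.FQFMU_CT


@dataclass
class PolarizableSite:
    """One MM interaction site.

    position : Angstrom; chi, eta, alpha : a.u.  ``alpha`` is required by
    the dipole-carrying variants and must be absent (None) for plain FQ.
    """

    position: np.ndarray
    element: str
    chi: float
    eta: float
    molecule_id: int
    alpha: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bad site position {self.position!r}")
        if self.eta <= 0:
            raise ParameterError(f"hardness must be positive, got {self.eta}")
        if self.alpha is not None and self.alpha <= 0:
            raise ParameterError(f"polarizability must be positive, got {self.alpha}")


@dataclass
class MMTopology:
    """Ordered MM sites partitioned into molecules with target net charges.

    ``molecule_charges`` maps molecule_id -> target net charge (a.u.);
    molecules missing from the map default to neutral.  ``system_charge``
    is the single global target used by the charge-transfer variant.
    """

    sites: list[PolarizableSite]
    molecule_charges: dict[int, float] = field(default_factory=dict)
    system_charge: float = 0.0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        """Site positions, Angstrom, shape (n, 3)."""
        return np.array([s.position for s in self.sites])

    @property
    def molecule_ids(self) -> list[int]:
        """Distinct molecule ids in order of first appearance."""
        seen: dict[int, None] = {}
        for s in self.sites:
            seen.setdefault(s.molecule_id, None)
        return list(seen)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def molecule_members(self) -> dict[int, np.ndarray]:
        """molecule_id -> array of site indices."""
        out: dict[int, list[int]] = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s.molecule_id, []).append(i)
        return {m: np.array(idx) for m, idx in out.items()}

    def target_charges(self) -> np.ndarray:
        """Per-molecule target net charges in molecule_ids order."""
        return np.array(
            [self.molecule_charges.get(m, 0.0) for m in self.molecule_ids]
        )

    def chi(self) -> np.ndarray:
        return np.array([s.chi for s in self.sites])

    def eta(self) -> np.ndarray:
        return np.array([s.eta for s in self.sites])

    def alpha(self) -> np.ndarray:
        a = [s.alpha for s in self.sites]
        if any(x is None for x in a):
            raise ParameterError("alpha missing on some sites")
        return np.array(a, dtype=float)

    def validate(self, variant: ForceFieldVariant) -> None:
        """Check geometry and parameter consistency for *variant*."""
        if self.n_sites == 0:
            raise ValueError("empty topology")
        pos = self.positions
        if self.n_sites > 1:
            d = scipy.spatial.distance.pdist(pos)
            if d.min() <= MIN_SITE_SEPARATION:
                i, j = _closest_pair(pos)
                raise DegenerateGeometryError(
                    f"sites {i} and {j} are {d.min():.4f} A apart "
                    f"(minimum {MIN_SITE_SEPARATION} A)"
                )
        has_alpha = [s.alpha is not None for s in self.sites]
        if variant.has_dipoles and not all(has_alpha):
            raise ParameterError(f"{variant.value} requires alpha on every site")
        if not variant.has_dipoles and any(has_alpha):
            raise ParameterError("FQ forbids alpha on sites")


def _closest_pair(pos: np.ndarray) -> tuple[int, int]:
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(pos))
    np.fill_diagonal(d, np.inf)
    return np.unravel_index(np.argmin(d), d.shape)  # type: ignore[return-value]


@dataclass
class ExternalSource:
    """Solute electrostatic potential and field sampled at the MM sites.

    potential : (n,) a.u.; field : (n, 3) a.u.  The field block is only
    consumed by the dipole-carrying variants but is always carried.
    """

    potential: np.ndarray
    field: np.ndarray

    def __post_init__(self):
        self.potential = np.asarray(self.potential, dtype=float)
        self.field = np.asarray(self.field, dtype=float)
        if self.potential.ndim != 1:
            raise ValueError("potential must be a 1-D array")
        if self.field.shape != (self.potential.size, 3):
            raise ValueError(
                f"field shape {self.field.shape} inconsistent with "
                f"{self.potential.size} sites"
            )

    @classmethod
    def zero(cls, n_sites: int) -> "ExternalSource":
        return cls(np.zeros(n_sites), np.zeros((n_sites, 3)))

    def check_topology(self, topology: MMTopology) -> None:
        if self.potential.size != topology.n_sites:
            raise ValueError(
                f"source has {self.potential.size} entries for "
                f"{topology.n_sites} sites"
            )


@dataclass
class KernelMatrices:
    """Interaction kernels of the saddle-point system.

    Tqq : (n, n) charge-charge, diagonal = per-site hardness.
    Tqmu : (n, 3n) charge-dipole coupling (None for FQ).
    Tmumu : (3n, 3n) dipole-dipole, diagonal 3x3 blocks = I/alpha (None for FQ).
    constraint_block : (n, m) molecule-indicator columns (m = 1 for the
    charge-transfer variant).
    """

    Tqq: np.ndarray
    constraint_block: np.ndarray
    Tqmu: np.ndarray | None = None
    Tmumu: np.ndarray | None = None


@dataclass
class LinearProblem:
    """Assembled symmetric saddle-point system A z = b with block layout
    z = (charges, multipliers, dipoles)."""

    matrix: np.ndarray
    rhs: np.ndarray
    n_sites: int
    n_constraints: int

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EmbeddingSolution:
    """Solved charges (a.u.), dipoles (a.u., None for FQ) and Lagrange
    multipliers, plus the linear-system residual norm."""

    charges: np.ndarray
    multipliers: np.ndarray
    dipoles: np.ndarray | None = None
    residual: float = 0.0

    @property
    def has_dipoles(self) -> bool:
        return self.dipoles is not None


# ---------------------------------------------------------------------------
# Kernel assembly
# ---------------------------------------------------------------------------

KERNEL_FORMS = ("ohno", "coulomb")


def _pair_geometry(positions_bohr: np.ndarray):
    """Displacements r_i - r_j (n,n,3) and distances (n,n), Bohr."""
    diff = positions_bohr[:, None, :] - positions_bohr[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    return diff, r


def build_kernels(
    topology: MMTopology,
    variant: ForceFieldVariant,
    kernel_form: str = "ohno",
) -> KernelMatrices:
    """Assemble the charge-charge / charge-dipole / dipole-dipole kernels.

    Two interaction forms are supported.  ``"ohno"`` (default) damps the
    Coulomb interaction at short range with a hardness-derived length,
    S(r) = 1/sqrt(r^2 + d_ij^2) with d_ij = 2/(eta_i + eta_j), the
    screening family conventionally paired with electronegativity-
    equalisation charges; ``"coulomb"`` uses the bare 1/r off-diagonals.
    Both reduce to 1/r at large separation.  The charge-dipole and
    dipole-dipole blocks are the consistent first and second derivatives
    of the same scalar kernel, so the FQ limit and the isolated-site
    mu = alpha * E limit both hold exactly.
    """
    if kernel_form not in KERNEL_FORMS:
        raise ValueError(f"unknown kernel form {kernel_form!r}; use one of {KERNEL_FORMS}")
    topology.validate(variant)

    n = topology.n_sites
    eta = topology.eta()
    pos = angstrom_to_bohr(topology.positions)
    diff, r = _pair_geometry(pos)
    off = ~np.eye(n, dtype=bool)

    if kernel_form == "ohno":
        d = 2.0 / (eta[:, None] + eta[None, :])
        u = r**2 + d**2
    else:
        u = r**2
    # u is strictly positive off-diagonal (validated geometry); guard the
    # diagonal so vectorised powers stay finite before being overwritten.
    u_safe = np.where(off, u, 1.0)

    Tqq = np.where(off, u_safe**-0.5, 0.0)
    np.fill_diagonal(Tqq, eta)

    cols = _constraint_columns(topology, variant)

    Tqmu = Tmumu = None
    if variant.has_dipoles:
        alpha = topology.alpha()
        # Induction acts only between molecules (polarization groups):
        # point dipoles at bond distances inside a rigid molecule would
        # couple catastrophically to their own molecule's charges, and the
        # intramolecular electrostatics is already encoded in chi/eta.
        mol = np.array([s.molecule_id for s in topology.sites])
        inter = off & (mol[:, None] != mol[None, :])
        # charge-dipole: T[i, 3j:3j+3] = (r_i - r_j) * u^-3/2
        g3 = np.where(inter, u_safe**-1.5, 0.0)
        Tqmu = (diff * g3[:, :, None]).reshape(n, 3 * n)
        # dipole-dipole: u^-3/2 * I - 3 u^-5/2 * (dr dr^T)
        g5 = np.where(inter, u_safe**-2.5, 0.0)
        blocks = g3[:, :, None, None] * np.eye(3) - 3.0 * g5[
            :, :, None, None
        ] * diff[:, :, :, None] * diff[:, :, None, :]
        inv_alpha = np.zeros((n, n))
        np.fill_diagonal(inv_alpha, 1.0 / alpha)
        blocks += inv_alpha[:, :, None, None] * np.eye(3)
        Tmumu = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)

    return KernelMatrices(Tqq=Tqq, constraint_block=cols, Tqmu=Tqmu, Tmumu=Tmumu)


def _constraint_columns(topology: MMTopology, variant: ForceFieldVariant) -> np.ndarray:
    n = topology.n_sites
    if variant.charge_transfer:
        return np.ones((n, 1))
    members = topology.molecule_members()
    ids = topology.molecule_ids
    cols = np.zeros((n, len(ids)))
    for k, m in enumerate(ids):
        cols[members[m], k] = 1.0
    return cols


# ---------------------------------------------------------------------------
# System assembly and solve
# ---------------------------------------------------------------------------


def assemble_system(
    kernels: KernelMatrices,
    topology: MMTopology,
    variant: ForceFieldVariant,
    source: ExternalSource,
) -> LinearProblem:
    """Build the symmetric saddle-point matrix and right-hand side.

    Block layout (charges q, multipliers lambda, dipoles mu):

        [ Tqq   C    Tqmu ] [ q  ]   [ -chi - V ]
        [ C^T   0    0    ] [ la ] = [  Qtot    ]
        [ Tqmu^T 0   Tmumu] [ mu ]   [  +E      ]

    For FQ the dipole rows and columns are removed.  The sign convention
    on the right-hand side (minus electronegativity and potential on the
    charge rows, plus field on the dipole rows) is fixed here and nowhere
    else.
    """
    source.check_topology(topology)
    n = topology.n_sites
    cols = kernels.constraint_block
    m = cols.shape[1]
    if kernels.Tqq.shape != (n, n) or cols.shape[0] != n:
        raise ValueError("kernel dimensions inconsistent with topology")

    if variant.has_dipoles:
        if kernels.Tqmu is None or kernels.Tmumu is None:
            raise ParameterError("dipole kernels missing for a dipole variant")
        dim = n + m + 3 * n
        A = np.zeros((dim, dim))
        b = np.zeros(dim)
        A[:n, :n] = kernels.Tqq
        A[:n, n : n + m] = cols
        A[n : n + m, :n] = cols.T
        A[:n, n + m :] = kernels.Tqmu
        A[n + m :, :n] = kernels.Tqmu.T
        A[n + m :, n + m :] = kernels.Tmumu
        b[n + m :] = source.field.ravel()
    else:
        dim = n + m
        A = np.zeros((dim, dim))
        b = np.zeros(dim)
        A[:n, :n] = kernels.Tqq
        A[:n, n:] = cols
        A[n:, :n] = cols.T

    b[:n] = -(topology.chi() + source.potential)
    if variant.charge_transfer:
        b[n : n + m] = topology.system_charge
    else:
        b[n : n + m] = topology.target_charges()
    return LinearProblem(matrix=A, rhs=b, n_sites=n, n_constraints=m)


def solve_embedding(
    topology: MMTopology,
    variant: ForceFieldVariant,
    source: ExternalSource | None = None,
    kernel_form: str = "ohno",
) -> EmbeddingSolution:
    """Solve the constrained electronegativity-equalisation system.

    Returns the charges, induced dipoles (dipole variants only) and
    Lagrange multipliers that make the quadratic energy stationary under
    the charge constraints.  Raises :class:`DegenerateGeometryError` if
    the assembled matrix is singular (e.g. coincident sites slipped
    through an externally-built topology).
    """
    if source is None:
        source = ExternalSource.zero(topology.n_sites)
    kernels = build_kernels(topology, variant, kernel_form)
    problem = assemble_system(kernels, topology, variant, source)
    A, b = problem.matrix, problem.rhs
    try:
        z = scipy.linalg.solve(A, b, assume_a="sym")
    except (scipy.linalg.LinAlgError, ValueError):
        z = None
    if z is None or not np.all(np.isfinite(z)):
        # pivoted (SVD) fallback for borderline conditioning
        z, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.linalg.norm(A @ z - b) / max(1.0, np.linalg.norm(b)))
    if residual > SOLVER_TOLERANCE:
        cond = np.linalg.cond(A)
        raise DegenerateGeometryError(
            f"saddle-point solve failed: relative residual {residual:.2e}, "
            f"condition number {cond:.2e} (dimension {problem.dimension})"
        )
    n, m = problem.n_sites, problem.n_constraints
    q = z[:n]
    lam = z[n : n + m]
    mu = z[n + m :].reshape(n, 3) if variant.has_dipoles else None
    return EmbeddingSolution(charges=q, multipliers=lam, dipoles=mu, residual=residual)


def interaction_energy(
    solution: EmbeddingSolution,
    source: ExternalSource,
    variant: ForceFieldVariant,
) -> float:
    """Solute-solvent electrostatic interaction energy, a.u.

    sum_i q_i V_i for FQ, minus sum_j mu_j . E_j for the dipole variants
    (the dipole term enters with a minus sign).
    """
    if solution.has_dipoles and not variant.has_dipoles:
        raise ParameterError("solution carries dipoles but variant is FQ")
    if variant.has_dipoles and not solution.has_dipoles:
        raise ParameterError(f"variant {variant.value} expects dipoles in the solution")
    e = float(solution.charges @ source.potential)
    if variant.has_dipoles:
        e -= float(np.sum(solution.dipoles * source.field))
    return e


# ---------------------------------------------------------------------------
# Point-charge solute source
# ---------------------------------------------------------------------------


def solute_point_source(
    solute_charges: Sequence[tuple[np.ndarray, float]],
    topology: MMTopology,
) -> ExternalSource:
    """Potential and field at the MM sites from a point-charge solute.

    ``solute_charges`` is a sequence of (position [Angstrom], charge
    [a.u.]) pairs.  V_i = sum_k c_k / |r_i - r_k| and
    E_i = sum_k c_k (r_i - r_k) / |r_i - r_k|^3 in atomic units.
    """
    pos_k = np.array([np.asarray(p, dtype=float) for p, _ in solute_charges])
    c_k = np.array([c for _, c in solute_charges], dtype=float)
    pos_i = topology.positions
    diff_ang = pos_i[:, None, :] - pos_k[None, :, :]
    dmin = np.linalg.norm(diff_ang, axis=-1).min() if len(c_k) else np.inf
    if dmin <= MIN_SOLUTE_SEPARATION:
        raise DegenerateGeometryError(
            f"solute site within {dmin:.3f} A of an MM site "
            f"(minimum {MIN_SOLUTE_SEPARATION} A)"
        )
    diff = angstrom_to_bohr(diff_ang)
    r = np.linalg.norm(diff, axis=-1)
    V = (c_k[None, :] / r).sum(axis=1)
    E = (c_k[None, :, None] * diff / r[:, :, None] ** 3).sum(axis=1)
    return ExternalSource(potential=V, field=E)


# ---------------------------------------------------------------------------
# Parameter sets and water topologies
# ---------------------------------------------------------------------------

#: Documented toy water parameter set used throughout the test-suite and as
#: the pipeline default (a.u.).  Hardnesses sit in the 0.5-1 a.u. range
#: typical of electronegativity-equalisation sets; polarizabilities sum to
#: ~10 bohr^3, close to the molecular polarizability of liquid water.
TOY_WATER = {
    "O": {"chi": 0.30, "eta": 0.60, "alpha": 5.0},
    "H": {"chi": 0.10, "eta": 0.90, "alpha": 2.5},
}

PARAMETER_SETS: dict[str, dict[str, dict[str, float]]] = {"toy": TOY_WATER}

#: Named templates for the published water parameterisations.  The numeric
#: values are NOT distributed with this package (they belong to the original
#: force-field publications); every entry is a placeholder that must be
#: filled in from a config file before use.
_TEMPLATE_NAMES = ("FQa", "FQb", "FQc", "FQFmu")


def template_parameter_set(name: str) -> dict:
    """Skeleton config for a named literature parameter set.

    All values are ``None`` placeholders; loading a config that still
    contains placeholders raises :class:`ParameterError`.
    """
    if name not in _TEMPLATE_NAMES:
        raise KeyError(f"unknown template {name!r}; known: {_TEMPLATE_NAMES}")
    return {
        "name": name,
        "note": "PLACEHOLDER VALUES - fill in from the published parameterisation",
        "O": {"chi": None, "eta": None, "alpha": None},
        "H": {"chi": None, "eta": None, "alpha": None},
    }


def water_topology(
    water_coords: np.ndarray,
    parameter_set: dict[str, dict[str, float]] | str = "toy",
    variant: ForceFieldVariant = ForceFieldVariant.FQ,
) -> MMTopology:
    """Build an MMTopology from rigid 3-site water coordinates.

    ``water_coords`` has shape (n_waters, 3, 3) ordered O, H, H, in
    Angstrom.  Each water is one neutral molecule.
    """
    if isinstance(parameter_set, str):
        parameter_set = PARAMETER_SETS[parameter_set]
    for el in ("O", "H"):
        vals = parameter_set.get(el, {})
        if any(vals.get(k) is None for k in ("chi", "eta")):
            raise ParameterError(f"parameter set has placeholder values for {el}")
    coords = np.asarray(water_coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != (3, 3):
        raise ValueError("water_coords must have shape (n_waters, 3, 3)")
    sites = []
    use_alpha = variant.has_dipoles
    for m, mol in enumerate(coords):
        for el, xyz in zip(("O", "H", "H"), mol):
            p = parameter_set[el]
            if use_alpha and p.get("alpha") is None:
                raise ParameterError(f"variant {variant.value} requires alpha for {el}")
            sites.append(
                PolarizableSite(
                    position=xyz,
                    element=el,
                    chi=p["chi"],
                    eta=p["eta"],
                    alpha=p["alpha"] if use_alpha else None,
                    molecule_id=m,
                )
            )
    return MMTopology(sites=sites)
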