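"""Unit and property tests for the constrained embedding solver."""

import numpy as np
import pytest

from fqspec import (
    DegenerateGeometryError,
    EmbeddingSolution,
    ExternalSource,
    ForceFieldVariant,
    MMTopology,
    ParameterError,
    PolarizableSite,
    build_kernels,
    assemble_system,
    interaction_energy,
    solute_point_source,
    solve_embedding,
    water_topology,
)
from fqspec.units import ANGSTROM_PER_BOHR, angstrom_to_bohr

from .conftest import random_water_cluster, tip3p_water
from .oracles import (
    brute_force_solve,
    naive_interaction_energy,
    naive_point_source,
    ohno_scalar,
    variational_energy,
)

FQ = ForceFieldVariant.FQ
FQFMU = ForceFieldVariant.FQFMU
FQFMU_CT = ForceFieldVariant.FQFMU_CT
ALL_VARIANTS = [FQ, FQFMU, FQFMU_CT]


def _site(pos, chi=0.2, eta=0.7, alpha=None, mol=0, element="X"):
    return PolarizableSite(position=np.asarray(pos, float), element=element,
                           chi=chi, eta=eta, alpha=alpha, molecule_id=mol)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kernel_form", ["ohno", "coulomb"])
def test_charge_kernel_reaches_coulomb_limit_at_large_r(kernel_form):
    """Off-diagonal Tqq tends to the bare 1/r at 100 bohr separation."""
    r_ang = 100.0 * ANGSTROM_PER_BOHR
    topo = MMTopology(sites=[_site([0, 0, 0], mol=0), _site([r_ang, 0, 0], mol=1)])
    k = build_kernels(topo, FQ, kernel_form)
    assert k.Tqq[0, 1] == pytest.approx(0.01, abs=1e-4)
    assert k.Tqq[0, 1] == k.Tqq[1, 0]


def test_single_site_kernel_is_hardness_self_term():
    topo = MMTopology(sites=[_site([0, 0, 0], eta=0.83)])
    k = build_kernels(topo, FQ)
    assert k.Tqq.shape == (1, 1)
    assert k.Tqq[0, 0] == 0.83


def test_water_kernel_matches_scalar_oracle(one_water):
    """Each matrix element equals an independent scalar evaluation."""
    topo = water_topology(one_water, "toy", FQ)
    k = build_kernels(topo, FQ, "ohno")
    pos = angstrom_to_bohr(topo.positions)
    eta = topo.eta()
    for i in range(3):
        for j in range(3):
            if i == j:
                expected = eta[i]
            else:
                expected = ohno_scalar(np.linalg.norm(pos[i] - pos[j]), eta[i], eta[j])
            assert k.Tqq[i, j] == pytest.approx(expected, abs=1e-12)


def test_kernel_symmetry_and_self_terms(two_waters):
    topo = water_topology(two_waters, "toy", FQFMU)
    k = build_kernels(topo, FQFMU)
    assert np.allclose(k.Tqq, k.Tqq.T)
    assert np.allclose(k.Tmumu, k.Tmumu.T)
    alpha = topo.alpha()
    for j in range(topo.n_sites):
        blk = k.Tmumu[3 * j : 3 * j + 3, 3 * j : 3 * j + 3]
        assert np.allclose(blk, np.eye(3) / alpha[j])


def test_overlapping_sites_rejected():
    topo = MMTopology(sites=[_site([0, 0, 0]), _site([0.05, 0, 0], mol=1)])
    with pytest.raises(DegenerateGeometryError):
        build_kernels(topo, FQ)


def test_missing_alpha_rejected(one_water):
    topo = water_topology(one_water, "toy", FQ)  # no alpha attached
    with pytest.raises(ParameterError):
        build_kernels(topo, FQFMU)


# ---------------------------------------------------------------------------
# Assembly dimensions
# ---------------------------------------------------------------------------


def test_assembled_dimensions(two_waters):
    n = 6
    topo_fq = water_topology(two_waters, "toy", FQ)
    p = assemble_system(build_kernels(topo_fq, FQ), topo_fq, FQ,
                        ExternalSource.zero(n))
    assert p.dimension == n + 2  # one constraint row per molecule

    topo_mu = water_topology(two_waters, "toy", FQFMU)
    p = assemble_system(build_kernels(topo_mu, FQFMU), topo_mu, FQFMU,
                        ExternalSource.zero(n))
    assert p.dimension == n + 2 + 3 * n

    topo_ct = water_topology(two_waters, "toy", FQFMU_CT)
    p = assemble_system(build_kernels(topo_ct, FQFMU_CT), topo_ct, FQFMU_CT,
                        ExternalSource.zero(n))
    assert p.n_constraints == 1  # single global row regardless of molecules
    assert p.dimension == n + 1 + 3 * n


def test_one_molecule_fq_dimension(one_water):
    topo = water_topology(one_water, "toy", FQ)
    p = assemble_system(build_kernels(topo, FQ), topo, FQ, ExternalSource.zero(3))
    assert p.matrix.shape == (4, 4)
    assert np.allclose(p.matrix, p.matrix.T)


def test_rhs_sign_convention(one_water):
    """Charge rows carry -(chi + V); dipole rows carry +E."""
    topo = water_topology(one_water, "toy", FQFMU)
    src = ExternalSource(np.array([0.1, 0.2, 0.3]),
                         np.tile([0.5, 0.0, -0.5], (3, 1)))
    p = assemble_system(build_kernels(topo, FQFMU), topo, FQFMU, src)
    assert np.allclose(p.rhs[:3], -(topo.chi() + src.potential))
    assert np.allclose(p.rhs[4:], src.field.ravel())


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------


def test_uniform_chi_zero_source_gives_zero_solution(one_water):
    sites = [
        _site(xyz, chi=0.25, eta=0.7, alpha=3.0, mol=0)
        for xyz in one_water[0]
    ]
    topo = MMTopology(sites=sites)
    sol = solve_embedding(topo, FQFMU)
    assert np.allclose(sol.charges, 0.0, atol=1e-12)
    assert np.allclose(sol.dipoles, 0.0, atol=1e-12)


@pytest.mark.parametrize("variant", ALL_VARIANTS)
def test_solve_matches_brute_force_minimizer(one_water, variant):
    """Toy water, zero source: saddle-point solve equals the constrained
    quadratic minimiser found by an independent optimiser."""
    topo = water_topology(one_water, "toy", variant)
    src = ExternalSource.zero(3)
    sol = solve_embedding(topo, variant, src)
    q_ref, mu_ref = brute_force_solve(topo, variant, src)
    assert np.max(np.abs(sol.charges - q_ref)) < 1e-8
    if variant.has_dipoles:
        assert np.max(np.abs(sol.dipoles - mu_ref)) < 1e-8


def test_charge_transfer_constraint_structure(two_waters):
    """Strong asymmetric source: per-molecule neutrality for FQFMU,
    equal-and-opposite molecular net charges for FQFMU_CT."""
    solute = [((1.5, 1.0, 1.0), 1.5)]
    for variant in (FQFMU, FQFMU_CT):
        topo = water_topology(two_waters, "toy", variant)
        src = solute_point_source(solute, topo)
        sol = solve_embedding(topo, variant, src)
        net = [sol.charges[3 * m : 3 * m + 3].sum() for m in range(2)]
        if variant is FQFMU:
            assert np.allclose(net, 0.0, atol=1e-10)
        else:
            assert abs(net[0] + net[1]) < 1e-10
            assert abs(net[0]) > 1e-4  # charge actually flowed


@pytest.mark.parametrize("variant", ALL_VARIANTS)
@pytest.mark.parametrize("trial", range(3))
def test_random_clusters_match_oracle(variant, trial):
    """Random <=4-molecule clusters: solve equals brute-force minimiser
    to 1e-8 per component and honours the constraints to 1e-10."""
    rng = np.random.default_rng(100 * trial + list(ForceFieldVariant).index(variant))
    coords = random_water_cluster(rng, int(rng.integers(2, 5)))
    topo = water_topology(coords, "toy", variant)
    solute = [(rng.uniform(-8, 8, 3) + np.array([0, 0, 12.0]), rng.uniform(-1, 1))]
    src = solute_point_source(solute, topo)
    sol = solve_embedding(topo, variant, src)
    q_ref, mu_ref = brute_force_solve(topo, variant, src)
    assert np.max(np.abs(sol.charges - q_ref)) < 1e-8
    if variant.has_dipoles:
        assert np.max(np.abs(sol.dipoles - mu_ref)) < 1e-8
    if variant.charge_transfer:
        assert abs(sol.charges.sum() - topo.system_charge) < 1e-10
    else:
        for idx in topo.molecule_members().values():
            assert abs(sol.charges[idx].sum()) < 1e-10


def test_solution_linear_in_source(two_waters):
    """Induced response obeys superposition: the source-dependent part of
    the solution is linear, solve(a V1 + V2) = a dq1 + dq2 + q0."""
    topo = water_topology(two_waters, "toy", FQFMU)
    s1 = solute_point_source([((0.0, 3.0, 0.0), 0.8)], topo)
    s2 = solute_point_source([((2.0, -3.0, 1.0), -0.5)], topo)
    both = ExternalSource(2.0 * s1.potential + s2.potential,
                          2.0 * s1.field + s2.field)
    sol0 = solve_embedding(topo, FQFMU)
    sola = solve_embedding(topo, FQFMU, s1)
    solb = solve_embedding(topo, FQFMU, s2)
    solc = solve_embedding(topo, FQFMU, both)
    expected_q = sol0.charges + 2.0 * (sola.charges - sol0.charges) \
        + (solb.charges - sol0.charges)
    expected_mu = sol0.dipoles + 2.0 * (sola.dipoles - sol0.dipoles) \
        + (solb.dipoles - sol0.dipoles)
    assert np.max(np.abs(solc.charges - expected_q)) < 1e-10
    assert np.max(np.abs(solc.dipoles - expected_mu)) < 1e-10


def test_mirror_symmetric_system_gives_mirror_solution():
    """Mirror-symmetric topology + source -> mirror-symmetric q and mu."""
    w = tip3p_water((0.0, 0.0, 2.0))  # water in the z>0 half-space
    w_mirror = w * np.array([1.0, 1.0, -1.0])
    topo = water_topology(np.array([w, w_mirror]), "toy", FQFMU)
    src = solute_point_source([((5.0, 0.0, 0.0), 1.0)], topo)  # on-plane charge
    sol = solve_embedding(topo, FQFMU, src)
    assert np.allclose(sol.charges[:3], sol.charges[3:], atol=1e-10)
    flip = np.array([1.0, 1.0, -1.0])
    assert np.allclose(sol.dipoles[:3], sol.dipoles[3:] * flip, atol=1e-10)


def test_isolated_site_dipole_is_alpha_times_field():
    """Single polarizable site with charge frozen at 0: mu = alpha E."""
    topo = MMTopology(sites=[_site([0, 0, 0], alpha=4.5)], molecule_charges={0: 0.0})
    e_field = np.array([[0.02, -0.01, 0.005]])
    src = ExternalSource(np.zeros(1), e_field)
    sol = solve_embedding(topo, FQFMU)
    assert np.allclose(sol.dipoles, 0.0)
    sol = solve_embedding(topo, FQFMU, src)
    assert sol.charges[0] == pytest.approx(0.0, abs=1e-14)
    assert np.allclose(sol.dipoles[0], 4.5 * e_field[0], atol=1e-14)


@pytest.mark.parametrize("variant", ALL_VARIANTS)
def test_energy_stationarity_under_constrained_perturbations(variant, two_waters):
    """No constraint-respecting +-1e-4 perturbation lowers the energy."""
    topo = water_topology(two_waters, "toy", variant)
    src = solute_point_source([((0.5, 4.0, 0.0), 1.0)], topo)
    sol = solve_embedding(topo, variant, src)
    u0 = variational_energy(topo, variant, src, sol.charges, sol.dipoles)
    rng = np.random.default_rng(5)
    members = list(topo.molecule_members().values())
    for _ in range(25):
        dq = rng.normal(0, 1e-4, topo.n_sites)
        if variant.charge_transfer:
            dq -= dq.sum() / dq.size
        else:
            for idx in members:
                dq[idx] -= dq[idx].sum() / idx.size
        dmu = None
        if variant.has_dipoles:
            dmu = sol.dipoles + rng.normal(0, 1e-4, sol.dipoles.shape)
        u = variational_energy(topo, variant, src, sol.charges + dq, dmu)
        assert u >= u0 - 1e-12


def test_singular_geometry_raises_diagnostic():
    sites = [_site([0, 0, 0]), _site([0.09, 0, 0], mol=0)]
    topo = MMTopology(sites=sites)
    with pytest.raises(DegenerateGeometryError):
        solve_embedding(topo, FQ)


# ---------------------------------------------------------------------------
# Interaction energy
# ---------------------------------------------------------------------------


def test_interaction_energy_examples():
    zero = EmbeddingSolution(charges=np.zeros(2), multipliers=np.zeros(1))
    src = ExternalSource(np.array([1.0, 2.0]), np.zeros((2, 3)))
    assert interaction_energy(zero, src, FQ) == 0.0

    sol = EmbeddingSolution(charges=np.array([0.1, -0.1]), multipliers=np.zeros(1))
    assert interaction_energy(sol, src, FQ) == pytest.approx(-0.1, abs=1e-15)


def test_interaction_energy_matches_naive_sum():
    rng = np.random.default_rng(42)
    q = rng.normal(size=5)
    mu = rng.normal(size=(5, 3))
    V = rng.normal(size=5)
    E = rng.normal(size=(5, 3))
    sol = EmbeddingSolution(charges=q, multipliers=np.zeros(1), dipoles=mu)
    src = ExternalSource(V, E)
    expected = naive_interaction_energy(q, mu, V, E)
    assert interaction_energy(sol, src, FQFMU) == pytest.approx(expected, abs=1e-12)


def test_interaction_energy_variant_mismatch():
    sol = EmbeddingSolution(charges=np.zeros(2), multipliers=np.zeros(1),
                            dipoles=np.zeros((2, 3)))
    src = ExternalSource(np.zeros(2), np.zeros((2, 3)))
    with pytest.raises(ParameterError):
        interaction_energy(sol, src, FQ)


# ---------------------------------------------------------------------------
# Point-charge source
# ---------------------------------------------------------------------------


def test_point_source_coulomb_law():
    """Unit charge at 2 bohr: V = 0.5 a.u., |E| = 0.25 a.u."""
    d_ang = 2.0 * ANGSTROM_PER_BOHR
    topo = MMTopology(sites=[_site([d_ang, 0, 0])])
    src = solute_point_source([((0.0, 0.0, 0.0), 1.0)], topo)
    assert src.potential[0] == pytest.approx(0.5, abs=1e-12)
    assert np.linalg.norm(src.field[0]) == pytest.approx(0.25, abs=1e-12)


def test_point_source_midpoint_of_dipole():
    """Opposite charges: V = 0 at the midpoint, E along the axis."""
    topo = MMTopology(sites=[_site([0, 0, 0])])
    src = solute_point_source([((-2.0, 0, 0), 1.0), ((2.0, 0, 0), -1.0)], topo)
    assert src.potential[0] == pytest.approx(0.0, abs=1e-14)
    assert abs(src.field[0][0]) > 0
    assert np.allclose(src.field[0][1:], 0.0, atol=1e-14)


def test_point_source_matches_naive_loop(two_waters):
    rng = np.random.default_rng(3)
    solute = [(rng.uniform(6, 9, 3), rng.uniform(-1, 1)) for _ in range(4)]
    topo = water_topology(np.concatenate([two_waters,
                                          [tip3p_water((-4.0, 1.0, 2.0))]]),
                          "toy", FQ)
    src = solute_point_source(solute, topo)
    V, E = naive_point_source(solute, topo.positions)
    assert np.max(np.abs(src.potential - V)) < 1e-12
    assert np.max(np.abs(src.field - E)) < 1e-12


def test_point_source_collision_rejected(one_water):
    topo = water_topology(one_water, "toy", FQ)
    with pytest.raises(DegenerateGeometryError):
        solute_point_source([((0.0, 0.1, 0.0), 1.0)], topo)
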