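"""Independent reference implementations used only by the tests.

These deliberately avoid the package's solution paths: the embedding
oracle minimises the explicit quadratic energy functional with a
general-purpose constrained optimiser instead of solving the saddle-point
system, and the electrostatics oracles are naive pairwise loops.
"""

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from fqspec.core import ExternalSource, ForceFieldVariant, MMTopology, build_kernels

BOHR = 0.529177210903


def energy_functional(topology, variant, source, kernel_form="ohno"):
    """Return U(z) over z = (q [, mu]) plus gradient/Hessian callables."""
    k = build_kernels(topology, variant, kernel_form)
    n = topology.n_sites
    if variant.has_dipoles:
        K = np.block([[k.Tqq, k.Tqmu], [k.Tqmu.T, k.Tmumu]])
        b = np.concatenate([topology.chi() + source.potential, -source.field.ravel()])
    else:
        K = k.Tqq
        b = topology.chi() + source.potential
    return K, b, k.constraint_block


def brute_force_solve(topology, variant, source, kernel_form="ohno"):
    """Constrained quadratic minimisation, independent of the package's
    saddle-point factorisation.

    A coarse minimum from a general-purpose constrained optimiser
    (trust-constr with exact derivatives) is refined by conjugate-
    gradient minimisation of the reduced quadratic in the constraint
    null space, starting from a feasible point — an iterative Krylov
    descent, not a direct solve of the package's KKT matrix.
    """
    K, b, cols = energy_functional(topology, variant, source, kernel_form)
    n = topology.n_sites
    dim = K.shape[0]
    A = np.zeros((cols.shape[1], dim))
    A[:, :n] = cols.T
    tgt = (
        np.array([topology.system_charge])
        if variant.charge_transfer
        else topology.target_charges()
    )
    res = minimize(
        lambda z: 0.5 * z @ K @ z + b @ z,
        np.zeros(dim),
        jac=lambda z: K @ z + b,
        hess=lambda z: K,
        method="trust-constr",
        constraints=[LinearConstraint(A, tgt, tgt)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 500},
    )
    z = _null_space_cg_refine(K, b, A, tgt, res.x)
    q = z[:n]
    mu = z[n:].reshape(n, 3) if variant.has_dipoles else None
    return q, mu


def _null_space_cg_refine(K, b, A, tgt, z_start):
    """Minimise the quadratic over {z : A z = tgt} by CG in the null space."""
    from scipy.linalg import null_space
    from scipy.sparse.linalg import LinearOperator, cg

    Z = null_space(A)
    # project the start onto the feasible manifold exactly
    z0, *_ = np.linalg.lstsq(A, tgt - A @ z_start, rcond=None)
    z0 = z_start + z0
    H = LinearOperator((Z.shape[1],) * 2, matvec=lambda y: Z.T @ (K @ (Z @ y)))
    g = Z.T @ (K @ z0 + b)
    y, info = cg(H, -g, rtol=1e-14, atol=1e-15, maxiter=20000)
    assert info == 0, "CG refinement did not converge"
    return z0 + Z @ y


def variational_energy(topology, variant, source, q, mu, kernel_form="ohno"):
    """Evaluate the quadratic functional at an arbitrary (q, mu)."""
    K, b, _ = energy_functional(topology, variant, source, kernel_form)
    z = q if mu is None else np.concatenate([q, mu.ravel()])
    return 0.5 * z @ K @ z + b @ z


def naive_point_source(solute, positions_ang):
    """Pairwise-loop potential and field (a.u.) at MM sites."""
    n = len(positions_ang)
    V = np.zeros(n)
    E = np.zeros((n, 3))
    for i, r_i in enumerate(positions_ang):
        for p, c in solute:
            d = (np.asarray(r_i) - np.asarray(p)) / BOHR
            r = np.linalg.norm(d)
            V[i] += c / r
            E[i] += c * d / r**3
    return V, E


def naive_interaction_energy(q, mu, V, E):
    """Term-by-term accumulation of sum qV - sum mu.E."""
    total = 0.0
    for qi, vi in zip(q, V):
        total += qi * vi
    if mu is not None:
        for mj, ej in zip(mu, E):
            total -= float(np.dot(mj, ej))
    return total


def ohno_scalar(r_bohr, eta_i, eta_j):
    """Scalar damped charge-charge kernel for element-wise checks."""
    d = 2.0 / (eta_i + eta_j)
    return 1.0 / np.sqrt(r_bohr**2 + d**2)
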