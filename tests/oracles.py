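"""Independent reference implementations used only by the tests.

Nothing here imports solver internals: the transport oracle assembles its
own finite-volume operator directly from the advection-diffusion equation
and integrates it exactly in time with a matrix exponential; the diffusion
series is the textbook eigenfunction solution; the collinearity oracle is
a brute-force eigen computation.
"""

import numpy as np
import scipy.linalg as sla


def diffusion_survival_fraction(D, L, t, n_terms=200):
    """Surviving mass fraction for pure diffusion of an initially uniform
    concentration in a slab: reflecting top, absorbing bottom.

    Eigenfunctions cos(lambda_n x), lambda_n = (2n+1) pi / (2 L); the
    surviving fraction is sum 8/((2n+1)^2 pi^2) exp(-D lambda_n^2 t).
    """
    n = np.arange(n_terms)
    lam = (2 * n + 1) * np.pi / (2.0 * L)
    return float(np.sum(8.0 / ((2 * n + 1) ** 2 * np.pi ** 2) * np.exp(-D * lam**2 * t)))


def _weights(nodes):
    w = np.empty_like(nodes)
    w[1:-1] = 0.5 * (nodes[2:] - nodes[:-2])
    w[0] = 0.5 * (nodes[1] - nodes[0])
    w[-1] = 0.5 * (nodes[-1] - nodes[-2])
    return w


def transport_reference(x_nodes, D, V, n0, t):
    """Exact-in-time solution of the semi-discrete single-size
    advection-diffusion column with zero total flux at the top and an
    absorbing bottom (bottom node pinned at zero).

    Finite-volume faces with upwind advection and central diffusion:
    F_{i+1/2} = max(V,0) N_i + min(V,0) N_{i+1} - D (N_{i+1} - N_i)/dx.
    Returns (profile over the interior nodes, surviving count).
    """
    x = np.asarray(x_nodes, dtype=float)
    n = x.size
    dx = x[1] - x[0]
    u = _weights(x)
    vp, vm = max(V, 0.0), min(V, 0.0)
    cD, cU = vp + D / dx, vm - D / dx

    m = n - 1  # interior unknowns; bottom node pinned to zero
    A = np.zeros((m, m))
    for i in range(m - 1):  # faces between unknowns
        A[i, i] -= cD / u[i]
        A[i, i + 1] -= cU / u[i]
        A[i + 1, i] += cD / u[i + 1]
        A[i + 1, i + 1] += cU / u[i + 1]
    A[m - 1, m - 1] -= cD / u[m - 1]  # face into the pinned bottom node

    prof = sla.expm(A * t) @ np.asarray(n0, dtype=float)[:m]
    return prof, float(u[:m] @ prof)


def brute_force_collinearity(S, subset):
    """1/sqrt(min eigenvalue of the Gram matrix of unit-normalized columns),
    via a direct dense eigen decomposition."""
    S = np.asarray(S, dtype=float)[:, list(subset)]
    Sn = S / np.sqrt((S**2).sum(axis=0))
    lam = np.linalg.eigvalsh(Sn.T @ Sn).min()
    return 1.0 / np.sqrt(max(lam, 1e-300))
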