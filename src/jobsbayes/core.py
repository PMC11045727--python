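"""Matrix-normal density, sparse Cholesky factors, and the prior map.

The model is Y ~ MN_{p,n}(0, Lambda, Sigma): a genes x cells matrix whose
row covariance Lambda captures gene co-expression and whose column
covariance Sigma captures spatial dependence between cells.  Sigma is never
formed directly; its precision is parameterized through the modified
Cholesky decomposition Sigma^{-1} = U D^{-1} U^T, with U unit upper
triangular and sparse because each ordered cell conditions only on its m
nearest ordered predecessors.  Column i of U stores regression coefficients:
the conditional mean of y_i given its neighbors is X_i u_i with residual
covariance d_i * Lambda, and U[g_m(i), i] = -u_i.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.sparse

from .ordering import MaximinOrder


@dataclasses.dataclass
class Theta:
    """Prior hyperparameters (theta1, theta2, theta3): marginal-variance-,
    range- and smoothness-related, all strictly positive."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if not (self.theta1 > 0 and self.theta2 > 0 and self.theta3 > 0):
            raise ValueError("all theta components must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])

    @classmethod
    def from_array(cls, a) -> "Theta":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclasses.dataclass
class GenePrior:
    """Inverse-Wishart prior IW(nu, Psi) on the gene covariance Lambda."""

    nu: float
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        p = self.psi.shape[0]
        if self.psi.shape != (p, p):
            raise ValueError("Psi must be square")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("Psi must be symmetric")
        if np.linalg.eigvalsh(self.psi).min() <= 0:
            raise ValueError("Psi must be positive definite")
        if not self.nu > p - 1:
            raise ValueError(f"need nu > p - 1 = {p - 1}")


@dataclasses.dataclass
class CholeskyFactors:
    """Per-column regression coefficients u_i and residual scales d_i.

    ``u[i]`` has length ``|g_m(i)|`` (empty for i = 0) and ``d[i] > 0``.
    Together with the neighbor sets these encode Sigma^{-1} = U D^{-1} U^T.
    """

    u: list[np.ndarray]
    d: np.ndarray
    order: MaximinOrder

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d <= 0):
            raise ValueError("all d_i must be positive")
        if len(self.u) != self.d.size:
            raise ValueError("u and d length mismatch")
        for i, (ui, g) in enumerate(zip(self.u, self.order.neighbors)):
            if len(ui) != g.size:
                raise ValueError(f"u[{i}] has {len(ui)} entries for {g.size} neighbors")

    @property
    def n(self) -> int:
        return self.d.size


def spd_cholesky(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Lower Cholesky factor, with a clear error on non-SPD input."""
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


def matrix_normal_logpdf(y: np.ndarray, lam: np.ndarray, sigma: np.ndarray) -> float:
    """Log density of Y ~ MN_{p,n}(0, Lambda, Sigma).

    Equals the multivariate-normal log density of vec(Y) (column stacking)
    with covariance kron(Sigma, Lambda).  Note the scale non-identifiability
    (c*Lambda, Sigma/c) for any c > 0.
    """
    y = np.asarray(y, dtype=float)
    p, n = y.shape
    ll = spd_cholesky(lam, "Lambda")
    ls = spd_cholesky(sigma, "Sigma")
    if ll.shape[0] != p or ls.shape[0] != n:
        raise ValueError("dimension mismatch between Y, Lambda, Sigma")
    # tr(Sigma^-1 Y^T Lambda^-1 Y) = ||L_lam^-1 Y L_sig^-T||_F^2
    a = scipy.linalg.solve_triangular(ll, y, lower=True)
    b = scipy.linalg.solve_triangular(ls, a.T, lower=True).T
    quad = float(np.sum(b * b))
    logdet_lam = 2.0 * float(np.sum(np.log(np.diag(ll))))
    logdet_sig = 2.0 * float(np.sum(np.log(np.diag(ls))))
    return -0.5 * (n * p * np.log(2.0 * np.pi) + n * logdet_lam + p * logdet_sig + quad)


def hyper_to_prior(
    theta: Theta, i: int, p: int, m_i: int
) -> tuple[float, float, np.ndarray]:
    """Map the three global hyperparameters to the column-i prior.

    Returns ``(alpha_i, beta_i, v_i)`` for the Normal-Inverse-Gamma prior on
    (u_i, d_i): alpha_i = 6, beta_i = 5*theta1*(1 - exp(-theta2 * i^(-1/p)))
    and diagonal prior variances v_ij = exp(-theta3*j) / (theta1*(1 -
    exp(-theta2 * i^(-1/p)))) for j = 1..m_i, with j indexing neighbors by
    increasing distance so far neighbors are shrunk hardest.

    ``i`` is the 1-based maximin order position; ``p`` the exponent base
    (gene count by default; spatial dimension if configured).
    """
    if i < 1:
        raise ValueError("order index i is 1-based")
    decay = 1.0 - np.exp(-theta.theta2 * float(i) ** (-1.0 / p))
    if decay <= 0.0:
        raise ValueError("beta_i underflowed to zero: theta2 too small (degenerate prior)")
    alpha_i = 6.0
    beta_i = 5.0 * theta.theta1 * decay
    j = np.arange(1, m_i + 1, dtype=float)
    v_i = np.exp(-theta.theta3 * j) / (theta.theta1 * decay)
    return alpha_i, float(beta_i), v_i


def regression_views(
    y_ordered: np.ndarray, order: MaximinOrder
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-column regression problems (y_i, X_i) in maximin order.

    ``y_i`` is column i of the ordered data; ``X_i`` stacks the neighbor
    columns g_m(i) in increasing-distance order (matching the prior decay
    index of :func:`hyper_to_prior`).
    """
    y_ordered = np.asarray(y_ordered, dtype=float)
    return [(y_ordered[:, i], y_ordered[:, g]) for i, g in enumerate(order.neighbors)]


def assemble_precision(cf: CholeskyFactors) -> scipy.sparse.csc_matrix:
    """Assemble the sparse spatial precision Sigma^{-1} = U D^{-1} U^T."""
    n = cf.n
    rows, cols, vals = [], [], []
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        g = cf.order.neighbors[i]
        rows.extend(g.tolist())
        cols.extend([i] * g.size)
        vals.extend((-np.asarray(cf.u[i], dtype=float)).tolist())
    u_mat = scipy.sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    d_inv = scipy.sparse.diags(1.0 / cf.d)
    prec = (u_mat @ d_inv @ u_mat.T).tocsc()
    return (prec + prec.T) * 0.5


def factors_to_correlation(cf: CholeskyFactors) -> np.ndarray:
    """Spatial correlation matrix implied by the factors.

    Inverts the assembled precision and rescales to unit diagonal.  Intended
    for desk-scale n; raises with a condition-number report if the implied
    covariance is numerically non-PD.
    """
    prec = assemble_precision(cf).toarray()
    try:
        l = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"assembled precision not PD (cond ~ {np.linalg.cond(prec):.3e})"
        ) from exc
    cov = scipy.linalg.cho_solve((l, True), np.eye(cf.n))
    s = np.sqrt(np.diag(cov))
    corr = cov / np.outer(s, s)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return corr


def factors_from_covariance(sigma: np.ndarray, order: MaximinOrder) -> CholeskyFactors:
    """Exact Gaussian conditional-regression factors of a given Sigma.

    For each ordered location i the coefficients are
    u_i = Sigma[g,g]^{-1} Sigma[g,i] and
    d_i = Sigma[i,i] - Sigma[i,g] u_i.  With m >= n-1 the assembled
    precision reproduces Sigma^{-1} exactly (the Vecchia factorization is
    exact at full conditioning).
    """
    sigma = np.asarray(sigma, dtype=float)
    u: list[np.ndarray] = []
    d = np.empty(order.n)
    for i, g in enumerate(order.neighbors):
        if g.size == 0:
            u.append(np.empty(0))
            d[i] = sigma[i, i]
            continue
        ui = np.linalg.solve(sigma[np.ix_(g, g)], sigma[g, i])
        u.append(ui)
        d[i] = sigma[i, i] - sigma[i, g] @ ui
    return CholeskyFactors(u=u, d=d, order=order)
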