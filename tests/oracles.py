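"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: Sobol indices come
from a Saltelli-type Monte-Carlo pick-and-freeze estimator on plain
random samples (no quadrature, no Hermite basis), and the Gauss-Hermite
nodes are recomputed from the Jacobi matrix of the three-term
recurrence by a dense eigenvalue solve.
"""

from __future__ import annotations

import numpy as np


def gauss_hermite_nodes_via_jacobi(n: int) -> np.ndarray:
    """Nodes of the n-point rule for the standard-normal weight.

    Eigenvalues of the symmetric Jacobi matrix of the probabilists'
    Hermite recurrence (off-diagonal sqrt(k)); independent of
    numpy.polynomial.
    """
    J = np.zeros((n, n))
    for k in range(1, n):
        J[k, k - 1] = J[k - 1, k] = np.sqrt(k)
    return np.sort(np.linalg.eigvalsh(J))


def saltelli_sobol(f, n: int, rng: np.random.Generator, n_blocks: int = 20):
    """Monte-Carlo main-effect and pairwise-interaction Sobol indices.

    ``f`` maps an (m, 3) array of standard-normal inputs to (m,)
    outputs.  Uses the pick-and-freeze estimator for first-order and
    closed pairwise effects; pure interactions are closed-pair minus
    the two mains.  Returns (est, se): dicts keyed by e.g. "S_w",
    "S_w_kappa", values in percent, with block-bootstrap standard
    errors from ``n_blocks`` independent replicates.
    """
    names = ("w", "kappa", "a")
    pairs = ((0, 1), (0, 2), (1, 2))
    nb = n // n_blocks
    keys = [f"S_{p}" for p in names] + [f"S_{names[i]}_{names[j]}" for i, j in pairs]
    blocks = {k: [] for k in keys}
    for _ in range(n_blocks):
        A = rng.standard_normal((nb, 3))
        B = rng.standard_normal((nb, 3))
        fA, fB = f(A), f(B)
        D = np.var(np.concatenate([fA, fB]))
        main = {}
        for i in range(3):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            main[i] = np.mean(fB * (f(ABi) - fA)) / D
            blocks[f"S_{names[i]}"].append(100.0 * main[i])
        for i, j in pairs:
            ABij = A.copy()
            ABij[:, [i, j]] = B[:, [i, j]]
            closed = np.mean(fB * (f(ABij) - fA)) / D
            blocks[f"S_{names[i]}_{names[j]}"].append(100.0 * (closed - main[i] - main[j]))
    est = {k: float(np.mean(v)) for k, v in blocks.items()}
    se = {k: float(np.std(v, ddof=1) / np.sqrt(n_blocks)) for k, v in blocks.items()}
    return est, se


def random_cubic(rng: np.random.Generator):
    """A random polynomial of total degree <= 3 in three variables.

    Returns (f, None); coefficients are O(1) so no single term
    dominates.
    """
    import itertools

    terms = [a for a in itertools.product(range(4), repeat=3) if sum(a) <= 3]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))

    def f(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        out = np.zeros(x.shape[0])
        for c, (i, j, k) in zip(coeffs, terms):
            out += c * x[:, 0] ** i * x[:, 1] ** j * x[:, 2] ** k
        return out

    return f


def mc_projection(f, alpha: tuple[int, ...], n: int, rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the orthonormal Hermite coefficient.

    c_alpha = E[f(xi) * psi_alpha(xi)] under the standard-normal
    measure, with psi built from numpy's Hermite-E evaluation rather
    than the package's recurrence.
    """
    import math

    from numpy.polynomial import hermite_e

    xi = rng.standard_normal((n, 3))
    psi = np.ones(n)
    for i, order in enumerate(alpha):
        c = np.zeros(order + 1)
        c[order] = 1.0
        psi *= hermite_e.hermeval(xi[:, i], c) / math.sqrt(math.factorial(order))
    return float(np.mean(f(xi) * psi))
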