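"""Independent exact Kalman filter for linear SDE models.

Discretizes dx = A x dt + diag(sigma) dW exactly per observation interval
(matrix exponential for the transition, Van Loan's method for the process
noise integral) and runs the textbook discrete-time Kalman recursion.  Kept
deliberately separate from the package's moment-propagation code so it can
serve as an oracle for it.
"""

import numpy as np
from scipy.linalg import expm


def discretize(A, Qc, dt):
    """Exact (F, Qd) for the linear SDE over a step dt (Van Loan)."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = Qc
    M[n:, n:] = A.T
    E = expm(M * dt)
    F = E[n:, n:].T
    Qd = F @ E[:n, n:]
    return F, 0.5 * (Qd + Qd.T)


def exact_kalman(A, sigma, H, R, x0, P0, times, ys, t0=0.0):
    """Discrete Kalman recursion with exact linear-SDE discretization.

    Returns (negative log-likelihood, updated means per time point).
    """
    n = A.shape[0]
    Qc = np.diag(np.asarray(sigma, dtype=float) ** 2)
    m, P = np.asarray(x0, float).copy(), np.asarray(P0, float).copy()
    t_prev = t0
    nll = 0.0
    means = []
    for t_k, y in zip(times, ys):
        F, Qd = discretize(A, Qc, t_k - t_prev)
        m = F @ m
        P = F @ P @ F.T + Qd
        S = H @ P @ H.T + np.atleast_2d(R)
        e = np.atleast_1d(y) - H @ m
        Sinv = np.linalg.inv(S)
        nll += 0.5 * (e @ Sinv @ e + np.log(np.linalg.det(2 * np.pi * S)))
        K = P @ H.T @ Sinv
        m = m + K @ e
        P = (np.eye(n) - K @ H) @ P
        means.append(m.copy())
        t_prev = t_k
    return nll, np.array(means)


def random_linear_setup(rng, n_max=3):
    """A random stable linear-Gaussian filtering problem."""
    n = int(rng.integers(1, n_max + 1))
    A = rng.normal(scale=0.3, size=(n, n))
    A[np.diag_indices(n)] = -rng.uniform(0.5, 1.5, size=n)
    sigma = rng.uniform(0.1, 0.8, size=n)
    m_obs = 1
    H = np.zeros((m_obs, n))
    H[0, 0] = 1.0
    R = np.array([[rng.uniform(0.05, 0.3) ** 2]])
    x0 = rng.normal(size=n)
    times = np.cumsum(rng.uniform(0.3, 0.6, size=8))
    ys = rng.normal(scale=1.0, size=(8, 1))
    return A, sigma, H, R, x0, times, ys


def as_dynmodel(A, sigma, H, x0):
    """Wrap the linear system as a package DynModel."""
    from topaug.model_core import DynModel

    n = A.shape[0]
    sig_names = [f"s{i}" for i in range(n)]

    def drift(x, u, theta, t):
        return A @ x

    return DynModel(
        name="lin",
        state_names=[f"x{i}" for i in range(n)],
        param_names=sig_names,
        drift=drift,
        drift_jac=lambda x, u, th, t: A,
        output_map=lambda x: H @ x,
        output_jac=lambda x: H,
        observable_names=[f"y{j}" for j in range(H.shape[0])],
        initial_state=np.asarray(x0, float),
        diffusion_params=sig_names,
    )
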