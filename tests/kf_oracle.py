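"""Independent closed-form linear Kalman measurement update, used as the
oracle for the central-difference update on affine problems.  Kept free of
any quitrate internals on purpose."""

import numpy as np


def linear_kf_update(x, P, H, b, R, y):
    """Posterior mean/cov for y = H x + b + noise, noise ~ N(0, R)."""
    x = np.asarray(x, float)
    P = np.asarray(P, float)
    H = np.atleast_2d(np.asarray(H, float))
    S = H @ P @ H.T + np.asarray(R, float)
    K = P @ H.T @ np.linalg.inv(S)
    x_post = x + K @ (np.asarray(y, float) - (H @ x + np.asarray(b, float)))
    P_post = P - K @ S @ K.T
    return x_post, 0.5 * (P_post + P_post.T)


def random_linear_problem(rng, dim_x=None, dim_y=None):
    """A random affine measurement with a random PSD prior."""
    nx = dim_x or rng.integers(1, 6)
    ny = dim_y or rng.integers(1, 6)
    A = rng.normal(size=(nx, nx))
    P = A @ A.T + 0.1 * np.eye(nx)
    x = rng.normal(size=nx)
    H = rng.normal(size=(ny, nx))
    b = rng.normal(size=ny)
    sd = rng.uniform(0.1, 2.0, size=ny)
    y = rng.normal(size=ny)
    return x, P, H, b, sd, y
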