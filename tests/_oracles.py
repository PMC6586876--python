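"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own optimization/projection code
paths: the subspace oracle is a dense grid search over the feasible frame
parameterization, and distance/variance oracles are naive coordinate-wise
computations.
"""

import numpy as np


def hypersphere_points(theta1, theta2, theta3):
    """Map S^3 hyperspherical angles to unit vectors in R^4 (batched)."""
    t1, t2, t3 = np.meshgrid(theta1, theta2, theta3, indexing="ij")
    t1, t2, t3 = t1.ravel(), t2.ravel(), t3.ravel()
    q = np.stack([
        np.cos(t1),
        np.sin(t1) * np.cos(t2),
        np.sin(t1) * np.sin(t2) * np.cos(t3),
        np.sin(t1) * np.sin(t2) * np.sin(t3),
    ], axis=1)
    return q, np.stack([t1, t2, t3], axis=1)


def _eval_objective(q, A, B, sa, sb):
    """J for frames (q1 = q, q2 = argmax in q's complement), batched.

    For fixed q1 the optimal second axis is the top eigenvector of
    (I - q q') B (I - q q'), so gridding q1 exhausts the feasible set.
    """
    t1 = np.einsum("ni,ij,nj->n", q, A, q) / sa
    Bq = q @ B
    qBq = np.einsum("ni,ni->n", Bq, q)
    M = (B[None, :, :]
         - q[:, :, None] * Bq[:, None, :]
         - Bq[:, :, None] * q[:, None, :]
         + qBq[:, None, None] * (q[:, :, None] * q[:, None, :]))
    lam = np.linalg.eigvalsh(M)[:, -1]
    return 0.5 * (t1 + lam / sb)


def two_frame_grid_oracle(A, B, sa, sb, coarse_deg=3.0, fine_deg=0.5):
    """Exhaustive coarse-to-fine grid search for d_prep = d_move = 1 in R^4.

    Returns the best objective found at an effective resolution of
    ``fine_deg`` degrees on the first-axis parameterization (the second
    axis is solved exactly per grid point).
    """
    c = np.radians(coarse_deg)
    th1 = np.arange(0.0, np.pi + c / 2, c)
    th2 = np.arange(0.0, np.pi + c / 2, c)
    th3 = np.arange(0.0, 2 * np.pi, c)
    q, angles = hypersphere_points(th1, th2, th3)
    vals = _eval_objective(q, A, B, sa, sb)
    best = angles[np.argmax(vals)]

    f = np.radians(fine_deg)
    span = np.radians(coarse_deg) * 1.5
    th1 = np.arange(best[0] - span, best[0] + span + f / 2, f)
    th2 = np.arange(best[1] - span, best[1] + span + f / 2, f)
    th3 = np.arange(best[2] - span, best[2] + span + f / 2, f)
    q, _ = hypersphere_points(th1, th2, th3)
    vals = _eval_objective(q, A, B, sa, sb)
    return float(vals.max())


def random_psd(rng, n, scale=1.0):
    """Random PSD matrix with eigenvalues on a decaying spectrum."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    ev = scale * rng.uniform(0.2, 1.0, n) * np.exp(-np.arange(n))
    return (Q * ev) @ Q.T
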