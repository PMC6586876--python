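"""Scoring estimated dimensions against the generator's ground truth.

Recovered quantities live in the analysis space — rates soft-normalized
per unit, optionally restricted to the trigger null-space — while the
generator's bases live in raw rate space.  A latent direction v in raw
space appears along D^-1 v after per-unit division by D = diag(divisors),
so all comparisons first push the ground-truth bases through the same
maps the pipeline applied, then use basis-free measures (cosine of the
best alignment, principal angles, captured-variance ratios).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orth, subspace_angles

from .synth import GroundTruth


def normalized_image(basis: np.ndarray, divisors: np.ndarray) -> np.ndarray:
    """Orthonormal basis of a raw-space subspace's image in normalized space."""
    B = np.atleast_2d(np.asarray(basis, float))
    if B.shape[0] == 1:
        B = B.T
    return orth(B / np.asarray(divisors, float)[:, None])


def trigger_axis_similarity(w: np.ndarray, truth: GroundTruth,
                            divisors: np.ndarray) -> float:
    """|cos angle| between decoder weights and the true trigger axis (both
    in normalized-rate space)."""
    img = normalized_image(truth.b_trig, divisors)[:, 0]
    w = np.asarray(w, float)
    return float(abs(w @ img) / np.linalg.norm(w))


def principal_angles_deg(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical angles between two subspaces, degrees, descending."""
    return np.degrees(subspace_angles(orth(np.asarray(A, float)),
                                      orth(np.asarray(B, float))))


def captured_variance(C: np.ndarray, Q: np.ndarray) -> float:
    """Variance of covariance C captured inside the subspace spanned by Q."""
    Qo = orth(np.asarray(Q, float))
    return float(np.trace(Qo.T @ C @ Qo))


def truth_basis_in_null(basis: np.ndarray, divisors: np.ndarray,
                        K: np.ndarray) -> np.ndarray:
    """Ground-truth subspace mapped into the trigger null-space coordinates."""
    img = normalized_image(basis, divisors)
    return orth(K.T @ img)
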