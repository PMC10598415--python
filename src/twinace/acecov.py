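"""Implied twin-pair covariance algebra for ACE-family models.

The classical biometric model decomposes a phenotype into additive-genetic
(A), shared-environmental (C) and non-shared-environmental (E) latent
factors with path coefficients a, c, e.  Across the members of a twin pair
the A factors correlate ``k_a`` (1 for MZ, 0.5 for DZ), the C factors
correlate 1, and the E factors are independent.  In the bivariate
correlated-factors model, same-component factors of the two traits
correlate rA, rC, rE.

This module is the single source of truth for the implied covariance: both
the simulator and the ML likelihoods build their matrices here.
"""

from __future__ import annotations

import numpy as np

K_A = {"MZ": 1.0, "DZ": 0.5, "DZ_SS": 0.5, "DZ_OS": 0.5}


def kinship_coefficient(zygosity: str) -> float:
    """Cross-twin additive-genetic correlation: 1 for MZ, 0.5 for DZ."""
    try:
        return K_A[zygosity]
    except KeyError:
        raise ValueError(f"unknown zygosity {zygosity!r}") from None


def univariate_pair_cov(a: float, c: float, e: float, k_a: float) -> np.ndarray:
    """2x2 covariance of (twin1, twin2) under paths (a, c, e)."""
    v = a * a + c * c + e * e
    b = k_a * a * a + c * c
    return np.array([[v, b], [b, v]])


def bivariate_pair_cov(paths1, paths2, r_a: float, r_c: float, r_e: float,
                       k_a: float) -> np.ndarray:
    """4x4 covariance of (x_twin1, y_twin1, x_twin2, y_twin2).

    ``paths1``/``paths2`` are (a, c, e) for the two traits.  The
    cross-twin cross-trait covariance carries no E term: non-shared
    environment is by definition uncorrelated across twins.
    """
    a1, c1, e1 = paths1
    a2, c2, e2 = paths2
    v1 = a1 * a1 + c1 * c1 + e1 * e1
    v2 = a2 * a2 + c2 * c2 + e2 * e2
    within = a1 * a2 * r_a + c1 * c2 * r_c + e1 * e2 * r_e
    cross_same1 = k_a * a1 * a1 + c1 * c1
    cross_same2 = k_a * a2 * a2 + c2 * c2
    ctct = k_a * a1 * a2 * r_a + c1 * c2 * r_c
    w = np.array([[v1, within], [within, v2]])
    b = np.array([[cross_same1, ctct], [ctct, cross_same2]])
    return np.block([[w, b], [b, w]])


def is_psd(mat: np.ndarray, tol: float = 1e-10) -> bool:
    lam = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    return bool(lam[0] >= -tol * max(1.0, abs(float(lam[-1]))))
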