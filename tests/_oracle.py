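"""Independent dense-grid oracle for the marginal likelihood.

Trapezoid integration of the per-person likelihood against the normal
latent density on a 20 001-point grid spanning +-10 person-SD. Kept free
of any package quadrature code so it can arbitrate the Gauss-Hermite path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def trapezoid_loglik(responses, easiness, person_sd, n_grid=20001, span=10.0) -> float:
    wide = responses.to_wide().to_numpy()
    easiness = np.asarray(easiness, dtype=float)
    grid = np.linspace(-span * person_sd, span * person_sd, n_grid)
    dens = norm.pdf(grid, scale=person_sd)
    P = 1.0 / (1.0 + np.exp(-(grid[:, None] + easiness[None, :])))
    total = 0.0
    for row in wide:
        like = np.ones_like(grid)
        for i, y in enumerate(row):
            if np.isnan(y):
                continue
            like = like * (P[:, i] if y == 1 else 1.0 - P[:, i])
        total += np.log(np.trapezoid(like * dens, grid))
    return float(total)


def trapezoid_prevalence(easiness, person_sd, n_grid=20001, span=10.0) -> float:
    grid = np.linspace(-span * person_sd, span * person_sd, n_grid)
    dens = norm.pdf(grid, scale=person_sd)
    p = 1.0 / (1.0 + np.exp(-(grid + easiness)))
    return float(np.trapezoid(p * dens, grid))
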