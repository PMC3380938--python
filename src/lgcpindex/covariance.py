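"""Separable space-time covariance blocks of the latent Gaussian prior.

Three independent blocks:

* space-time field:  sigma^2 * Rs(alpha) (x) Rt(beta)   (Kronecker product,
  Rs = exp(-alpha * dx_km) over cell centroids, Rt = exp(-beta * |dy|) over years)
* year effect:       sigma_y^2 * Rt(beta)
* nugget:            sigma0^2 * I over samples

A small jitter is added to correlation diagonals before factorisation.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .params import ModelParams


def _corr_factor(R: np.ndarray, what: str):
    """Cholesky of a correlation matrix, with an informative PD error."""
    try:
        return sla.cholesky(R, lower=True)
    except sla.LinAlgError:
        lam = float(np.linalg.eigvalsh(R).min())
        raise np.linalg.LinAlgError(
            f"{what} correlation matrix not positive definite "
            f"(smallest eigenvalue {lam:.3e}); increase jitter") from None


class CovarianceStructure:
    """Correlation factors, inverses and log-determinants for one parameter point.

    Parameters
    ----------
    params : ModelParams
    dist_km : (C, C) array of great-circle distances between cell centroids.
    n_years : number of years in the latent field.
    jitter : added to correlation diagonals before factorisation.
    """

    def __init__(self, params: ModelParams, dist_km: np.ndarray, n_years: int,
                 jitter: float = 1e-8):
        self.params = params
        self.dist_km = np.asarray(dist_km, dtype=float)
        self.n_years = int(n_years)
        self.jitter = float(jitter)

        self.year_lag = np.abs(np.subtract.outer(np.arange(n_years), np.arange(n_years))
                               ).astype(float)
        self.Rs = np.exp(-params.alpha * self.dist_km) + jitter * np.eye(len(self.dist_km))
        self.Rt = np.exp(-params.beta * self.year_lag) + jitter * np.eye(n_years)

        self.Ls = _corr_factor(self.Rs, "spatial")
        self.Lt = _corr_factor(self.Rt, "temporal")
        eye_s = np.eye(len(self.Rs))
        eye_t = np.eye(n_years)
        self.Rs_inv = sla.cho_solve((self.Ls, True), eye_s)
        self.Rt_inv = sla.cho_solve((self.Lt, True), eye_t)
        self.logdet_Rs = 2.0 * float(np.sum(np.log(np.diag(self.Ls))))
        self.logdet_Rt = 2.0 * float(np.sum(np.log(np.diag(self.Lt))))

    # -- covariance blocks (dense; used by simulation and reference paths) --

    def field_cov(self) -> np.ndarray:
        """sigma^2 * Rs (x) Rt over (cell, year) pairs, cell-major ordering."""
        return self.params.sigma_sq * np.kron(self.Rs, self.Rt)

    def year_cov(self) -> np.ndarray:
        return self.params.sigma_y_sq * self.Rt

    def nugget_cov(self, n: int) -> np.ndarray:
        return self.params.sigma0_sq * np.eye(n)

    # -- derivative helpers (w.r.t. log decay rates) ------------------------

    def dRs_dlogalpha(self) -> np.ndarray:
        return -self.params.alpha * self.dist_km * self.Rs

    def dRt_dlogbeta(self) -> np.ndarray:
        return -self.params.beta * self.year_lag * self.Rt

    def logdet_field_cov(self) -> float:
        m1 = len(self.Rs) * self.n_years
        return (m1 * np.log(self.params.sigma_sq)
                + self.n_years * self.logdet_Rs + len(self.Rs) * self.logdet_Rt)

    def logdet_year_cov(self) -> float:
        return self.n_years * np.log(self.params.sigma_y_sq) + self.logdet_Rt
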