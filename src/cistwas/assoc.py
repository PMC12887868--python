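"""Kinship-corrected association of expression components with responses.

The variance components of the null model

    response = mu + g + e,  g ~ N(0, K*sigma_g2),  e ~ N(0, I*sigma_e2)

are estimated once per response by profiled REML in the eigenbasis of the
kinship matrix.  Each predictor (a gene's cis-EC or trans-EC) is then tested
one at a time by generalized least squares at those fixed variance
components — the usual one-pass mixed-model scan approximation — with a
Wald z statistic against a normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import KinshipMatrix
from .reml import EigenGRM, profile_reml_ratio

__all__ = ["AssocStat", "NullModel", "fit_null", "test_component", "dual_association"]

P_FLOOR = 1e-300


@dataclass
class AssocStat:
    beta: float
    se: float
    zscore: float
    p: float
    degenerate: bool = False


@dataclass
class NullModel:
    trait_name: str
    sigma_g2: float
    sigma_e2: float
    individual_ids: list[str]
    eigenvalues: np.ndarray   # eigenvalues of K on the analyzed individuals
    basis: np.ndarray         # eigenvectors (columns), orthonormal
    y_rot: np.ndarray         # rotated response
    one_rot: np.ndarray       # rotated intercept

    @property
    def weights(self) -> np.ndarray:
        """Diagonal of V = sigma_g2*K + sigma_e2*I in the eigenbasis."""
        d = self.sigma_g2 * self.eigenvalues + self.sigma_e2
        return np.maximum(d, 1e-12 * max(self.sigma_g2 + self.sigma_e2, 1e-12))


def fit_null(response: np.ndarray, K: KinshipMatrix, trait_name: str = "",
             min_n: int = 30) -> NullModel:
    """REML null model for one response under kinship covariance K.

    Individuals with missing response must already be removed; K must be
    restricted to the same individuals, positive semidefinite up to
    tolerance.
    """
    y = np.asarray(response, dtype=float)
    if len(y) < min_n:
        raise ValueError(f"only {len(y)} non-missing individuals (minimum {min_n})")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values after missing-data removal")
    if np.var(y) <= 0:
        raise ValueError("response has zero variance")
    K.check_psd()
    eig = EigenGRM.build(K.values, y)
    vg, ve, _ = profile_reml_ratio(eig)
    return NullModel(trait_name=trait_name, sigma_g2=vg, sigma_e2=ve,
                     individual_ids=list(K.individual_ids),
                     eigenvalues=eig.s, basis=eig.U,
                     y_rot=eig.y_rot, one_rot=eig.one_rot)


def test_component(null: NullModel, predictor: np.ndarray) -> AssocStat:
    """GLS single-predictor test at the null model's variance components.

    Fits response = mu + beta*predictor + g + e with (sigma_g2, sigma_e2)
    held at the null fit; zscore = beta/se and p = 2*Phi(-|z|), floored at
    1e-300.  A zero-variance predictor yields a flagged record with p = 1.
    """
    x = np.asarray(predictor, dtype=float)
    if len(x) != len(null.y_rot):
        raise ValueError("predictor not aligned to the null model's individuals")
    if np.var(x) <= 0 or not np.isfinite(x).all():
        return AssocStat(beta=0.0, se=np.inf, zscore=0.0, p=1.0, degenerate=True)
    d = null.weights
    x_rot = null.basis.T @ x
    X = np.column_stack([null.one_rot, x_rot])
    Xw = X / d[:, None]
    xtvx = X.T @ Xw
    xtvy = Xw.T @ null.y_rot
    try:
        cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return AssocStat(beta=0.0, se=np.inf, zscore=0.0, p=1.0, degenerate=True)
    beta = cov @ xtvy
    se = float(np.sqrt(cov[1, 1]))
    z = float(beta[1]) / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), P_FLOOR))
    return AssocStat(beta=float(beta[1]), se=se, zscore=z, p=p)


def dual_association(null: NullModel, cis_ec: np.ndarray,
                     trans_ec: np.ndarray) -> tuple[AssocStat, AssocStat]:
    """Independent single-predictor tests of a gene's cis-EC and trans-EC."""
    return test_component(null, cis_ec), test_component(null, trans_ec)
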