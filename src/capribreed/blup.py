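"""BLUP breeding values, prediction error, reliability and accuracy.

At converged variance components, Henderson's mixed-model equations yield
BLUEs of the fixed effects and predicted breeding values (PBV) for every
pedigree animal, record-holding or not — a record-less buck is predicted
entirely through his relatives.  The diagonal of the inverse coefficient
matrix gives each animal's prediction error variance PEV = C^aa_ii * s2e;
SEP = sqrt(PEV), reliability R_AP = 1 - SEP^2/sigma_a2 and accuracy
RTi = sqrt(R_AP).  Confidence ranges PBV +/- k*SEP carry the usual normal
coverage (68% at k=1, 95% at k=2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import Pedigree, a_inverse_sparse
from .reml import (
    ModelSpec,
    VarianceComponents,
    build_design_matrices,
)
from sklearn.base import BaseEstimator

#: accuracy interpretation bands (lower-inclusive), fractions of 1
ACCURACY_BANDS = (
    (0.90, "true-BV-grade"),
    (0.75, "medium/high"),
    (0.50, "medium"),
    (0.00, "preliminary"),
)
#: reliability interpretation bands (lower-inclusive)
RELIABILITY_BANDS = (
    (0.90, "very reliable"),
    (0.75, "good"),
    (0.65, "more than sufficient"),
    (0.55, "sufficient"),
    (0.30, "poor"),
    (0.00, "unreliable"),
)


@dataclass
class MMESolution:
    """Solved mixed-model equations for one trait at fixed components."""

    blue: pd.DataFrame  # fixed-effect estimates with level names
    pbv: np.ndarray  # additive predictions, one per pedigree animal
    pe: np.ndarray  # permanent-environment solutions (recorded does)
    pev: np.ndarray  # prediction error variance per pedigree animal
    components: VarianceComponents
    x_columns: list


def solve_blup(
    X, Z_a, Z_pe, y, A_inv, vc: VarianceComponents, x_columns=None
):
    """Solve Henderson's MME at the given variance components.

    ``X`` may have zero columns (all-random model with a known mean already
    subtracted from ``y``).  Returns an MMESolution with PEV from the exact
    inverse of the coefficient matrix (dense factorization; systems beyond a
    few thousand equations are solved the same way, block by block).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z_a = sparse.csr_matrix(Z_a)
    Z_pe = sparse.csr_matrix(Z_pe)
    y = np.asarray(y, dtype=float)
    p, q, npe = X.shape[1], Z_a.shape[1], Z_pe.shape[1]
    lam_a = vc.sigma_e2 / vc.sigma_a2
    lam_pe = vc.sigma_e2 / vc.sigma_pe2 if npe and vc.sigma_pe2 > 0 else None
    use_pe = npe > 0 and vc.sigma_pe2 > 0
    blocks = [sparse.csr_matrix(X), Z_a] + ([Z_pe] if use_pe else [])
    W = sparse.hstack(blocks).tocsr() if blocks else sparse.csr_matrix((len(y), 0))
    m = W.shape[1]
    C = (W.T @ W).toarray()
    sl_u = slice(p, p + q)
    C[sl_u, sl_u] += lam_a * A_inv.toarray()
    if use_pe:
        C[p + q :, p + q :] += lam_pe * np.eye(npe)
    rhs = W.T @ y
    cho = linalg.cho_factor(C, lower=True, check_finite=False)
    theta = linalg.cho_solve(cho, rhs, check_finite=False)
    Cinv, info = linalg.lapack.dpotri(cho[0], lower=True)
    Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
    pev = np.diag(Cinv)[sl_u] * vc.sigma_e2
    names = x_columns if x_columns is not None else [f"x{j}" for j in range(p)]
    blue = pd.DataFrame({"effect": names, "estimate": theta[:p]})
    return MMESolution(
        blue=blue,
        pbv=theta[sl_u],
        pe=theta[p + q :] if use_pe else np.zeros(0),
        pev=pev,
        components=vc,
        x_columns=list(names),
    )


def prediction_error_variance(solution: MMESolution) -> np.ndarray:
    """SEP per pedigree animal: sqrt of the PEV diagonal."""
    return np.sqrt(solution.pev)


def reliability_accuracy(sep, sigma_a2: float, inbreeding=None, tol: float = 1e-6):
    """R_AP = 1 - SEP^2/sigma_a2 (clipped to [0, 1]) and RTi = sqrt(R_AP).

    SEP^2 exceeding sigma_a2*(1+F) beyond tolerance is a scaling defect in
    the caller's inputs; it is warned about and clipped.
    """
    sep = np.asarray(sep, dtype=float)
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    bound = sigma_a2 * (1.0 + (np.zeros_like(sep) if inbreeding is None else np.asarray(inbreeding)))
    if np.any(sep**2 > bound * (1 + tol)):
        warnings.warn("SEP^2 exceeds sigma_a2*(1+F); reliability clipped at 0")
    r_ap = np.clip(1.0 - sep**2 / sigma_a2, 0.0, 1.0)
    return r_ap, np.sqrt(r_ap)


def confidence_range(pbv, sep, k: float = 2.0):
    """PBV +/- k*SEP with its nominal normal coverage.

    Returns (lower, upper, coverage); k=1 -> 68.3%, k=2 -> 95.4%.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    from scipy.stats import norm

    pbv = np.asarray(pbv, dtype=float)
    sep = np.asarray(sep, dtype=float)
    coverage = float(2.0 * norm.cdf(k) - 1.0)
    return pbv - k * sep, pbv + k * sep, coverage


def _band(value: float, bands) -> str:
    for lo, label in bands:
        if value >= lo:
            return label
    return bands[-1][1]


def interpret_scores(rti=None, r_ap=None):
    """Categorical interpretation of accuracy and/or reliability scores.

    Band boundaries are lower-inclusive (0.50 accuracy reads "medium").
    Returns a dict with the labels that were requested.
    """
    out = {}
    if rti is not None:
        out["accuracy_band"] = _band(float(rti), ACCURACY_BANDS)
    if r_ap is not None:
        out["reliability_band"] = _band(float(r_ap), RELIABILITY_BANDS)
    return out


class BLUPEvaluator(BaseEstimator):
    """Per-animal genetic evaluation at fixed variance components.

    Parameters mirror AnimalModelREML's model declaration plus the variance
    components to plug in (dict trait -> VarianceComponents, e.g. from
    fitted AnimalModelREML instances).

    Attributes (after ``fit``)
    --------------------------
    evaluation_ : DataFrame with one row per pedigree animal x trait:
        animal_id, sex, trait, pbv, sep, rti, r_ap, accuracy_band,
        reliability_band, n_records, n_offspring.
    blue_ : dict trait -> fixed-effect BLUE table.
    solutions_ : dict trait -> MMESolution.
    """

    def __init__(
        self,
        traits=("milk", "fat", "protein", "dm"),
        include_genotype=True,
        fixed_factors=None,
        age_col="age_months",
        variance_components=None,
    ):
        self.traits = traits
        self.include_genotype = include_genotype
        self.fixed_factors = fixed_factors
        self.age_col = age_col
        self.variance_components = variance_components

    def fit(self, records: pd.DataFrame, y=None, *, pedigree: Pedigree = None):
        if pedigree is None:
            raise ValueError("fit requires pedigree=<Pedigree>")
        if self.variance_components is None:
            raise ValueError("variance_components must be provided")
        spec = ModelSpec(
            traits=tuple(self.traits),
            include_genotype=self.include_genotype,
            fixed_factors=self.fixed_factors,
            age_col=self.age_col,
        )
        design = build_design_matrices(records, spec, pedigree)
        A_inv = a_inverse_sparse(pedigree)
        n_rec = np.asarray(design.Z_a.sum(axis=0)).ravel().astype(int)
        n_off = pedigree.offspring_counts()
        rows = []
        self.solutions_ = {}
        self.blue_ = {}
        for t in self.traits:
            vc = self.variance_components[t]
            sol = solve_blup(
                design.X, design.Z_a, design.Z_pe, design.y[t], A_inv, vc,
                x_columns=design.x_columns,
            )
            self.solutions_[t] = sol
            self.blue_[t] = sol.blue
            sep = prediction_error_variance(sol)
            r_ap, rti = reliability_accuracy(sep, vc.sigma_a2, pedigree.inbreeding)
            for i, aid in enumerate(pedigree.ids):
                rows.append(
                    {
                        "animal_id": aid,
                        "sex": pedigree.sex[i],
                        "trait": t,
                        "pbv": sol.pbv[i],
                        "sep": sep[i],
                        "rti": rti[i],
                        "r_ap": r_ap[i],
                        "accuracy_band": _band(rti[i], ACCURACY_BANDS),
                        "reliability_band": _band(r_ap[i], RELIABILITY_BANDS),
                        "n_records": n_rec[i],
                        "n_offspring": n_off[i],
                    }
                )
        self.evaluation_ = pd.DataFrame(rows)
        self.design_ = design
        self._ped_index_ = dict(pedigree.index)
        return self

    def predict(self, animal_ids, trait=None):
        """PBVs for the requested animals (first fitted trait by default)."""
        trait = trait or self.traits[0]
        sol = self.solutions_[trait]
        return np.array([sol.pbv[self._ped_index_[str(a)]] for a in animal_ids])
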