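"""Model-true simulation studies used to validate the evaluation machinery.

The central check: in data generated exactly from the animal model, the
prediction error variances reported by the mixed-model equations are the
true error variances, so PBV +/- 1*SEP should cover ~68% of true breeding
values and PBV +/- 2*SEP ~95%.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .blup import prediction_error_variance, solve_blup
from .pedigree import DOE, a_inverse_sparse
from .reml import VarianceComponents
from .simulate import SimulationConfig, simulate_pedigree, simulate_true_breeding_values

#: study variance components for 210-day milk yield (kg^2)
MILK_COMPONENTS = VarianceComponents(11511.83, 1689.51, 15578.23)


def sep_coverage_study(
    seed: int,
    n_replicates: int = 10,
    n_founders: int = 200,
    n_generations: int = 3,
    generation_size: int = 200,
    records_per_doe: tuple = (1, 3),
    components: VarianceComponents = MILK_COMPONENTS,
    mean: float = 416.0,
) -> dict:
    """Empirical coverage of PBV +/- k*SEP for k = 1, 2.

    Each replicate simulates a ~600-animal 3-generation pedigree, draws
    milk TBVs and 1-3 repeated records per doe under an overall-mean-only
    model, solves the MME at the true components, and scores the fraction
    of all pedigree animals whose TBV falls inside the confidence range.
    Returns {"coverage_1sep": %, "coverage_2sep": %, "n_animals": total}.
    """
    vc = components
    vcd = {
        t: {"sigma_a2": vc.sigma_a2, "sigma_pe2": vc.sigma_pe2,
            "sigma_e2": vc.sigma_e2}
        for t in ("milk", "fat", "protein", "dm")
    }
    cov1, cov2 = [], []
    total = 0
    for rep in range(n_replicates):
        rep_seed = (seed + 1) * 1000 + rep
        cfg = SimulationConfig(
            n_founders=n_founders,
            n_generations=n_generations,
            generation_size=generation_size,
            seed=rep_seed,
        )
        ped = simulate_pedigree(cfg)
        tbv = simulate_true_breeding_values(ped, vcd, seed=rep_seed + 1)[
            "tbv_milk"
        ].to_numpy()
        rng = np.random.default_rng(rep_seed + 2)
        does = [i for i in range(len(ped)) if ped.sex[i] == DOE]
        rec = np.repeat(
            does, rng.integers(records_per_doe[0], records_per_doe[1] + 1, len(does))
        )
        n = len(rec)
        pe = {a: rng.normal(0, np.sqrt(vc.sigma_pe2)) for a in does}
        y = (
            mean
            + tbv[rec]
            + np.array([pe[a] for a in rec])
            + rng.normal(0, np.sqrt(vc.sigma_e2), n)
        )
        X = np.ones((n, 1))
        Z_a = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), rec)), shape=(n, len(ped))
        )
        ids = sorted(set(rec))
        pos = {a: k for k, a in enumerate(ids)}
        Z_pe = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), [pos[a] for a in rec])),
            shape=(n, len(ids)),
        )
        sol = solve_blup(X, Z_a, Z_pe, y, a_inverse_sparse(ped), vc)
        sep = prediction_error_variance(sol)
        err = np.abs(tbv - sol.pbv)
        cov1.append(100.0 * np.mean(err <= sep))
        cov2.append(100.0 * np.mean(err <= 2.0 * sep))
        total += len(ped)
    return {
        "coverage_1sep": float(np.mean(cov1)),
        "coverage_2sep": float(np.mean(cov2)),
        "n_animals": total,
        "per_replicate_2sep": cov2,
        "per_replicate_1sep": cov1,
    }
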