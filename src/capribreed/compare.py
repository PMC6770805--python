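"""Comparison of the genotype-inclusive and genotype-exclusive evaluations.

The question the two-model contrast answers: does acknowledging the CSN1S1
genotype as a fixed effect change the variance partition (heritability) and
re-rank the predicted breeding values?  The machinery: PBV descriptive
statistics by sex, Pearson correlations and OLS regressions between the two
models' PBVs (over all pedigree animals and, separately, over phenotyped
does), and per-trait heritability deltas with propagated SEs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pbv_descriptives_by_sex(evaluation: pd.DataFrame) -> pd.DataFrame:
    """Min/max/median/adjusted skewness/kurtosis per sex x trait x parameter.

    `evaluation` is a BLUPEvaluator.evaluation_ table (or concatenation of
    two model variants with a ``model`` column).
    """
    params = [c for c in ("pbv", "sep", "rti", "r_ap") if c in evaluation.columns]
    group_cols = [c for c in ("model", "sex", "trait") if c in evaluation.columns]
    rows = []
    for keys, grp in evaluation.groupby(group_cols, sort=True):
        if len(grp) == 0:
            raise ValueError("empty sex stratum")
        base = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        for p in params:
            v = grp[p].to_numpy(dtype=float)
            rows.append(
                {
                    **base,
                    "parameter": p,
                    "minimum": v.min(),
                    "maximum": v.max(),
                    "median": float(np.median(v)),
                    "skewness": float(stats.skew(v, bias=False)) if len(v) > 2 else np.nan,
                    "kurtosis": float(stats.kurtosis(v, bias=False)) if len(v) > 3 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pbv_correlation(pbv_a, pbv_b):
    """Pearson r between two models' PBVs with its two-sided t-test p."""
    a = np.asarray(pbv_a, dtype=float)
    b = np.asarray(pbv_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance PBV vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def pbv_regression(pbv_a, pbv_b):
    """OLS of model-b PBVs on model-a PBVs: slope, intercept, R^2."""
    a = np.asarray(pbv_a, dtype=float)
    b = np.asarray(pbv_b, dtype=float)
    if a.std() == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def heritability_delta(result_incl, result_excl):
    """h2(including genotype) - h2(excluding genotype) with propagated SE.

    Accepts REMLResult-like objects with ``h2`` and ``h2_se`` attributes.
    """
    delta = result_incl.h2 - result_excl.h2
    se = float(np.sqrt(result_incl.h2_se**2 + result_excl.h2_se**2))
    return float(delta), se


def comparison_report(
    eval_incl: pd.DataFrame,
    eval_excl: pd.DataFrame,
    traits=("milk", "fat", "protein", "dm"),
    phenotyped_ids=None,
) -> dict:
    """Full two-model comparison.

    Returns {"correlations": per-trait r/p/slope/intercept/R2 over all
    pedigree animals (and over `phenotyped_ids` when given),
    "descriptives": the by-sex summary table of both variants}.
    """
    frames = []
    for name, ev in (("incl_genotype", eval_incl), ("excl_genotype", eval_excl)):
        e = ev.copy()
        e["model"] = name
        frames.append(e)
    both = pd.concat(frames, ignore_index=True)
    desc = pbv_descriptives_by_sex(both)

    rows = []
    for t in traits:
        a = eval_incl.loc[eval_incl["trait"] == t].set_index("animal_id")["pbv"]
        b = eval_excl.loc[eval_excl["trait"] == t].set_index("animal_id")["pbv"]
        common = a.index.intersection(b.index)
        subsets = {"all_pedigree": common}
        if phenotyped_ids is not None:
            subsets["phenotyped"] = common.intersection(pd.Index(phenotyped_ids))
        for pop, ids in subsets.items():
            av, bv = a.loc[ids].to_numpy(), b.loc[ids].to_numpy()
            r, p = pbv_correlation(av, bv)
            slope, intercept, r2 = pbv_regression(av, bv)
            rows.append(
                {
                    "trait": t,
                    "population": pop,
                    "n": len(ids),
                    "pearson_r": r,
                    "p_value": p,
                    "slope": slope,
                    "intercept": intercept,
                    "r_squared": r2,
                }
            )
    return {"correlations": pd.DataFrame(rows), "descriptives": desc}
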