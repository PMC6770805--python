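"""Synthetic herdbook generator: pedigrees, CSN1S1 genotypes, lactations.

Everything downstream of data collection is testable against this module:
it simulates a random-mating goat pedigree, drops single-locus alpha-s1
casein genotypes through it by Mendelian inheritance, draws true breeding
values from the additive model TBV ~ MVN(0, A (x) G0) by recursive gene
flow, and emits repeated 210-day lactation records from the exact linear
model the evaluation fits (farm, parturition year/month/season, birth type,
genotype, linear+quadratic age, animal, permanent environment, residual).

Default variance components, trait means, factor level counts and genotype
classes are the study conditions of the Murciano-Granadina evaluation this
package reproduces; they are configurable but not meant to be tuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import BUCK, DOE, Pedigree, validate_pedigree

TRAITS = ("milk", "fat", "protein", "dm")

#: 210-day breed reference means (kg): milk, fat, protein, dry matter
TRAIT_MEANS = {"milk": 416.0, "fat": 19.54, "protein": 13.25, "dm": 52.33}

#: additive / permanent-environment / residual variances per trait (kg^2),
#: the genotype-inclusive estimates used as simulation truth
VARIANCE_COMPONENTS = {
    "milk": {"sigma_a2": 11511.83, "sigma_pe2": 1689.51, "sigma_e2": 15578.23},
    "fat": {"sigma_a2": 16.87, "sigma_pe2": 16.22, "sigma_e2": 25.74},
    "protein": {"sigma_a2": 9.45, "sigma_pe2": 0.36, "sigma_e2": 8.14},
    "dm": {"sigma_a2": 57.45, "sigma_pe2": 82.03, "sigma_e2": 211.58},
}

#: genetic correlations among (milk, fat, protein, dm)
GENETIC_CORR = np.array(
    [
        [1.00, 0.01, -0.02, 0.01],
        [0.01, 1.00, 0.97, -0.09],
        [-0.02, 0.97, 1.00, 0.14],
        [0.01, -0.09, 0.14, 1.00],
    ]
)
#: environmental correlations (used for both PE and residual channels)
ENVIRONMENTAL_CORR = np.array(
    [
        [1.00, 0.01, -0.02, 0.01],
        [0.01, 1.00, 0.97, -0.09],
        [-0.02, 0.97, 1.00, 0.14],
        [0.01, -0.09, 0.14, 1.00],
    ]
)

ALLELES = ("A", "B", "E", "F", "N")

#: alpha-s1 casein output per allele, g per litre of milk: strong alleles
#: (A, B) ~3.6, medium (E) ~1.6, weak (F) ~0.6, null (N) 0
ALLELE_CASEIN_G_PER_L = {"A": 3.6, "B": 3.6, "E": 1.6, "F": 0.6, "N": 0.0}

#: the genotype-class labels observed in the breed, written in the breed
#: association's conventional order (BA, not AB)
GENOTYPE_CLASS_LABELS = {
    frozenset(["A"]): "AA",
    frozenset(["A", "B"]): "BA",
    frozenset(["B"]): "BB",
    frozenset(["A", "E"]): "AE",
    frozenset(["B", "E"]): "BE",
    frozenset(["E", "F"]): "EF",
}

MONTHS = (5, 6, 7, 8, 9, 10, 11, 12)  # May..December kidding months
YEARS = tuple(range(2005, 2017))
SEASONS = ("spring", "summer", "autumn", "winter")
BIRTH_TYPES = (1, 2, 3, 4, 5)
N_FARMS = 59


def genotype_class(a1: str, a2: str) -> str:
    """Class label of an unordered allele pair (BA convention for observed classes)."""
    key = frozenset((a1, a2))
    if key in GENOTYPE_CLASS_LABELS:
        return GENOTYPE_CLASS_LABELS[key]
    return "".join(sorted((a1, a2)))


def default_genotype_effects() -> dict:
    """Per-class additive shifts (kg per 210-day lactation) on each trait.

    Scaled from the per-allele casein outputs: a genotype's expected alpha-s1
    yield in g/L (mean of its two alleles) times the 416 L reference lactation
    gives its casein kg; the class shift is that kg centred on the population
    mean class.  Placeholder magnitudes in the absence of published per-class
    fixed-effect estimates; fully configurable.
    """
    pairs = [(a, b) for i, a in enumerate(ALLELES) for b in ALLELES[i:]]
    raw = {}
    for a, b in pairs:
        gpl = 0.5 * (ALLELE_CASEIN_G_PER_L[a] + ALLELE_CASEIN_G_PER_L[b])
        raw[genotype_class(a, b)] = gpl * 416.0 / 1000.0  # g/L -> kg protein
    centre = np.mean(list(raw.values()))
    effects = {}
    for cls, kg in raw.items():
        shift = kg - centre
        effects[cls] = {"milk": 0.0, "fat": 0.0, "protein": shift, "dm": shift}
    return effects


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic herdbook.

    Defaults mirror the evaluated population: 59 farms, kidding years
    2005-2016 and months May-December, four seasons, birth types 1-5, six
    observed genotype classes, 1-6 lactations per doe, and the
    genotype-inclusive variance components as simulation truth.
    """

    n_founders: int = 200
    n_generations: int = 3
    generation_size: int = 200
    does_per_buck: int = 20
    lactations_per_doe: tuple = (1, 6)
    allele_freqs: dict = field(
        default_factory=lambda: {a: 1.0 / len(ALLELES) for a in ALLELES}
    )
    genotype_effects: dict = field(default_factory=default_genotype_effects)
    variance_components: dict = field(
        default_factory=lambda: {t: dict(VARIANCE_COMPONENTS[t]) for t in TRAITS}
    )
    trait_means: dict = field(default_factory=lambda: dict(TRAIT_MEANS))
    genetic_corr: np.ndarray = field(default_factory=lambda: GENETIC_CORR.copy())
    environmental_corr: np.ndarray = field(
        default_factory=lambda: ENVIRONMENTAL_CORR.copy()
    )
    n_farms: int = N_FARMS
    years: tuple = YEARS
    months: tuple = MONTHS
    birth_types: tuple = BIRTH_TYPES
    #: SD of each fixed-effect level distribution, as a fraction of the
    #: trait's phenotypic SD
    effect_scales: dict = field(
        default_factory=lambda: {
            "farm": 0.25,
            "year": 0.10,
            "month": 0.08,
            "season": 0.05,
            "birth_type": 0.08,
        }
    )
    #: linear and quadratic regression on age in months, per trait
    age_coeffs: dict = field(
        default_factory=lambda: {
            "milk": (1.2, -0.010),
            "fat": (0.05, -0.0004),
            "protein": (0.04, -0.0003),
            "dm": (0.15, -0.0012),
        }
    )
    #: first-parturition age (months): truncated-normal mean/sd and the
    #: observed bounds of the study sample
    age_first_mean: float = 24.0
    age_first_sd: float = 8.0
    age_bounds: tuple = (14.03, 130.13)
    #: Wood lactation-curve shape (b, c) for test-day disaggregation;
    #: peak at b/c = 50 days, typical for dairy goats
    wood_shape: tuple = (0.2, 0.004)
    seed: int = 20190913

    def __post_init__(self):
        tot = sum(self.allele_freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {tot}, not 1")
        for t, vc in self.variance_components.items():
            for k, v in vc.items():
                if v < 0:
                    raise ValueError(f"negative variance {k}={v} for trait {t}")
        for M in (self.genetic_corr, self.environmental_corr):
            M = np.asarray(M)
            if not np.allclose(M, M.T):
                raise ValueError("correlation matrix not symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError("correlation matrix not positive semi-definite")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random-mating multi-generation pedigree, reproducible under the seed.

    Founders are unrelated; each later generation draws a sire uniformly
    from all earlier bucks and a dam from all earlier does.  The buck
    fraction is 1/(does_per_buck + 1).
    """
    rng = np.random.default_rng(config.seed)
    buck_frac = 1.0 / (config.does_per_buck + 1)
    rows = []
    bucks, does = [], []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"G{counter:06d}"

    n_buck_founders = max(1, round(config.n_founders * buck_frac))
    for i in range(config.n_founders):
        aid = new_id()
        sex = BUCK if i < n_buck_founders else DOE
        (bucks if sex == BUCK else does).append(aid)
        rows.append((aid, "", "", sex, 2005))
    if not bucks or not does:
        raise ValueError("need at least one founder of each sex")
    for g in range(1, config.n_generations):
        new_bucks, new_does = [], []
        for _ in range(config.generation_size):
            aid = new_id()
            sire = bucks[rng.integers(len(bucks))]
            dam = does[rng.integers(len(does))]
            sex = BUCK if rng.random() < buck_frac else DOE
            (new_bucks if sex == BUCK else new_does).append(aid)
            rows.append((aid, sire, dam, sex, 2005 + g))
        bucks += new_bucks
        does += new_does
    return validate_pedigree(rows)


def drop_genotypes(ped: Pedigree, allele_freqs=None, seed: int = 0) -> pd.DataFrame:
    """Drop a single-locus genotype through the pedigree.

    Founders are drawn from Hardy-Weinberg proportions at `allele_freqs`;
    every non-founder inherits one uniformly chosen allele from each known
    parent (an unknown parent contributes a fresh population allele).
    Returns a table (animal_id, allele1, allele2, genotype_class).
    """
    if allele_freqs is None:
        allele_freqs = {a: 1.0 / len(ALLELES) for a in ALLELES}
    tot = sum(allele_freqs.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {tot}, not 1")
    rng = np.random.default_rng(seed)
    alleles = list(allele_freqs)
    probs = np.array([allele_freqs[a] for a in alleles])
    n = len(ped)
    a1 = np.empty(n, dtype=object)
    a2 = np.empty(n, dtype=object)

    def pop_allele():
        return alleles[rng.choice(len(alleles), p=probs)]

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a1[i] = (a1[s] if rng.random() < 0.5 else a2[s]) if s >= 0 else pop_allele()
        a2[i] = (a1[d] if rng.random() < 0.5 else a2[d]) if d >= 0 else pop_allele()
    cls = [genotype_class(x, y) for x, y in zip(a1, a2)]
    return pd.DataFrame(
        {"animal_id": ped.ids, "allele1": a1, "allele2": a2, "genotype_class": cls}
    )


def polymorphism_summary(marker_matrix) -> float:
    """Percentage of polymorphic markers: 100 x (m - monomorphic) / m.

    A marker is monomorphic when a single allele is observed across all
    genotype calls.  `marker_matrix` is animals x markers; each call is a
    2-character string or a pair of alleles.
    """
    mat = np.asarray(marker_matrix, dtype=object)
    if mat.size == 0:
        raise ValueError("empty marker matrix")
    if mat.ndim == 1:
        mat = mat[:, None]
    n_mono = 0
    for j in range(mat.shape[1]):
        seen = set()
        for call in mat[:, j]:
            seen.update(call)
        if len(seen) <= 1:
            n_mono += 1
    m = mat.shape[1]
    return 100.0 * (m - n_mono) / m


def _g0_matrix(variance_components: dict, genetic_corr) -> np.ndarray:
    sd = np.array([np.sqrt(variance_components[t]["sigma_a2"]) for t in TRAITS])
    return np.asarray(genetic_corr) * np.outer(sd, sd)


def simulate_true_breeding_values(
    ped: Pedigree, variance_components=None, genetic_corr=None, seed: int = 0
) -> pd.DataFrame:
    """True breeding values ~ MVN(0, A (x) G0) by recursive gene flow.

    Founders are drawn from N(0, G0); each non-founder is the mean of its
    known parents' TBVs plus a Mendelian-sampling deviation with variance
    d_i * G0, where d_i is the within-family variance scalar (inbreeding
    aware).  Exact and O(n), no A factorisation needed.
    """
    if variance_components is None:
        variance_components = VARIANCE_COMPONENTS
    if genetic_corr is None:
        genetic_corr = GENETIC_CORR
    G0 = _g0_matrix(variance_components, genetic_corr)
    w, V = np.linalg.eigh(G0)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("G0 not positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    n = len(ped)
    k = len(TRAITS)
    tbv = np.zeros((n, k))
    F = ped.inbreeding
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mu = 0.5 * (tbv[s] + tbv[d])
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = max(s, d)
            mu = 0.5 * tbv[p]
            di = 0.75 - 0.25 * F[p]
        else:
            mu = 0.0
            di = 1.0
        tbv[i] = mu + np.sqrt(di) * (L @ z[i])
    out = pd.DataFrame(tbv, columns=[f"tbv_{t}" for t in TRAITS])
    out.insert(0, "animal_id", ped.ids)
    return out


def _mvn_draws(rng, corr, sds, size):
    cov = np.asarray(corr) * np.outer(sds, sds)
    w, V = np.linalg.eigh(cov)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return rng.standard_normal((size, len(sds))) @ L.T


def _season_of_month(month: int) -> str:
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "autumn"
    return "winter"


def simulate_lactation_dataset(
    ped: Pedigree,
    genotypes: pd.DataFrame = None,
    config: SimulationConfig = None,
    tbv: pd.DataFrame = None,
) -> pd.DataFrame:
    """Repeated 210-day lactation records from the full animal model.

    Each doe receives a farm, a first-parturition age, a number of
    lactations in the configured range, and per-parity records
    y = mu + farm + year + month + season + birth type + genotype + b1*age
    + b2*age^2 + TBV + PE + e, generated jointly over the four trait
    channels.  PE is constant across a doe's lactations; e is fresh per
    record; ages advance roughly a year per parity.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)
    if tbv is None:
        tbv = simulate_true_breeding_values(
            ped, config.variance_components, config.genetic_corr, seed=config.seed + 2
        )
    if genotypes is None:
        genotypes = drop_genotypes(ped, config.allele_freqs, seed=config.seed + 3)
    tbv_arr = tbv.set_index("animal_id").loc[ped.ids].to_numpy()
    geno_cls = genotypes.set_index("animal_id").loc[ped.ids, "genotype_class"].to_numpy()

    sds = np.array(
        [np.sqrt(sum(config.variance_components[t].values())) for t in TRAITS]
    )
    mu = np.array([config.trait_means[t] for t in TRAITS])

    # level-effect draws, one table per factor, per trait channel
    levels = {
        "farm": [f"F{k + 1:02d}" for k in range(config.n_farms)],
        "year": list(config.years),
        "month": list(config.months),
        "season": list(SEASONS),
        "birth_type": list(config.birth_types),
    }
    effects = {}
    for fac, lv in levels.items():
        scale = config.effect_scales[fac]
        effects[fac] = {
            v: rng.standard_normal(len(TRAITS)) * scale * sds for v in lv
        }

    pe_sds = np.array(
        [np.sqrt(config.variance_components[t]["sigma_pe2"]) for t in TRAITS]
    )
    e_sds = np.array(
        [np.sqrt(config.variance_components[t]["sigma_e2"]) for t in TRAITS]
    )
    b1 = np.array([config.age_coeffs[t][0] for t in TRAITS])
    b2 = np.array([config.age_coeffs[t][1] for t in TRAITS])

    doe_idx = [i for i in range(len(ped)) if ped.sex[i] == DOE]
    pe_draws = _mvn_draws(rng, config.environmental_corr, pe_sds, len(doe_idx))
    lo, hi = config.lactations_per_doe
    rows = []
    for k, i in enumerate(doe_idx):
        farm = levels["farm"][rng.integers(config.n_farms)]
        age = float(
            np.clip(
                rng.normal(config.age_first_mean, config.age_first_sd),
                *config.age_bounds,
            )
        )
        year = int(rng.choice(config.years))
        n_lact = int(rng.integers(lo, hi + 1))
        gcls = geno_cls[i]
        gshift = config.genotype_effects.get(gcls, {})
        gvec = np.array([gshift.get(t, 0.0) for t in TRAITS])
        for parity in range(1, n_lact + 1):
            month = int(rng.choice(config.months))
            season = _season_of_month(month)
            btype = int(rng.choice(config.birth_types))
            e = _mvn_draws(rng, config.environmental_corr, e_sds, 1)[0]
            y = (
                mu
                + effects["farm"][farm]
                + effects["year"][year]
                + effects["month"][month]
                + effects["season"][season]
                + effects["birth_type"][btype]
                + gvec
                + b1 * age
                + b2 * age**2
                + tbv_arr[i]
                + pe_draws[k]
                + e
            )
            rows.append(
                {
                    "doe_id": ped.ids[i],
                    "parity": parity,
                    "farm": farm,
                    "year": year,
                    "month": month,
                    "season": season,
                    "birth_type": btype,
                    "genotype_class": gcls,
                    "age_months": round(age, 2),
                    "milk_kg": y[0],
                    "fat_kg": y[1],
                    "protein_kg": y[2],
                    "dm_kg": y[3],
                }
            )
            age += float(rng.normal(12.0, 1.0))
            year = min(year + 1, config.years[-1])
    return pd.DataFrame(rows)


def wood_curve(t, total_kg, b=0.25, c=0.006, days=210):
    """Wood incomplete-gamma daily yield a*t^b*exp(-c t), scaled so the
    continuous integral over (0, days] equals `total_kg`."""
    from scipy.special import gamma, gammainc

    t = np.asarray(t, dtype=float)
    if c > 0:
        # integral of t^b e^{-ct} over (0, days]: gamma(b+1)/c^(b+1) * P(b+1, c*days)
        integral = gamma(b + 1) / c ** (b + 1) * gammainc(b + 1, c * days)
    else:
        integral = days ** (b + 1) / (b + 1)
    a = total_kg / integral
    return a * t**b * np.exp(-c * t)


def simulate_test_day_records(
    lactation_row, config: SimulationConfig = None
) -> pd.DataFrame:
    """Disaggregate one 210-day lactation into 7 monthly test-day records.

    Emits daily milk yields at days 30, 60, ..., 210 following the Wood
    curve whose 210-day integral equals the record's total, with component
    percentages constant across the lactation (so the standardized totals
    round-trip).
    """
    if config is None:
        config = SimulationConfig()
    b, c = config.wood_shape
    row = lactation_row if isinstance(lactation_row, dict) else dict(lactation_row)
    days = np.arange(30, 211, 30)
    daily = wood_curve(days, row["milk_kg"], b=b, c=c)
    milk = max(row["milk_kg"], 1e-12)
    return pd.DataFrame(
        {
            "doe_id": row["doe_id"],
            "parity": row["parity"],
            "day_in_milk": days,
            "daily_milk_kg": daily,
            "fat_pct": 100.0 * row["fat_kg"] / milk,
            "protein_pct": 100.0 * row["protein_kg"] / milk,
            "dm_pct": 100.0 * row["dm_kg"] / milk,
        }
    )


def simulate_test_day_dataset(
    lactations: pd.DataFrame, config: SimulationConfig = None
) -> pd.DataFrame:
    """Apply `simulate_test_day_records` to every lactation row."""
    parts = [
        simulate_test_day_records(row, config) for _, row in lactations.iterrows()
    ]
    return pd.concat(parts, ignore_index=True)
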