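import numpy as np
import pytest

from capribreed.pedigree import validate_pedigree
from capribreed.simulate import (
    SimulationConfig,
    drop_genotypes,
    simulate_lactation_dataset,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def trio_pedigree():
    return validate_pedigree(
        [
            ("S1", "", "", "buck", 2000),
            ("D1", "", "", "doe", 2000),
            ("X", "S1", "D1", "doe", 2001),
        ]
    )


@pytest.fixture(scope="session")
def fullsib_pedigree():
    """Sire x dam -> two full sibs -> their inbred offspring."""
    return validate_pedigree(
        [
            ("S", "", "", "buck", 2000),
            ("D", "", "", "doe", 2000),
            ("B1", "S", "D", "buck", 2001),
            ("D2", "S", "D", "doe", 2001),
            ("K", "B1", "D2", "doe", 2002),
        ]
    )


def random_pedigree(n, seed, p_known=0.8):
    """Random valid pedigree of n animals with ~p_known parent links."""
    rng = np.random.default_rng(seed)
    rows = []
    bucks, does = [], []
    for i in range(n):
        aid = f"A{i:03d}"
        sire = dam = ""
        if bucks and rng.random() < p_known:
            sire = bucks[rng.integers(len(bucks))]
        if does and rng.random() < p_known:
            dam = does[rng.integers(len(does))]
        sex = "buck" if rng.random() < 0.3 else "doe"
        (bucks if sex == "buck" else does).append(aid)
        rows.append((aid, sire, dam, sex, 2000 + i // 10))
    return validate_pedigree(rows)


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated population shared by the slower model-fitting tests."""
    cfg = SimulationConfig(
        n_founders=80,
        n_generations=3,
        generation_size=80,
        lactations_per_doe=(1, 3),
        seed=20190913,
    )
    ped = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg.allele_freqs, seed=cfg.seed + 3)
    records = simulate_lactation_dataset(ped, geno, cfg)
    return cfg, ped, geno, records
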