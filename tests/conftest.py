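import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from diffmet import preprocess, simulate
from diffmet.types import AbundanceTable, Status

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-condition cohort (planted shifts and pairs), seed 1."""
    cfg = simulate.default_study_config(seed=1)
    metadata, table, truth = simulate.generate_cohort(cfg)
    return cfg, metadata, table, truth


@pytest.fixture
def tiny_abundance():
    """2 animals x 1 tissue x 2 replicates x 3 metabolites, complete."""
    rows = []
    for animal in ("a1", "a2"):
        for rep in (1, 2):
            for k, met in enumerate(("ala", "gly", "ser")):
                rows.append(
                    {
                        "animal_id": animal,
                        "tissue": "cerebellum",
                        "replicate": rep,
                        "metabolite": met,
                        "raw_abundance": 10.0 + k + (animal == "a2") + 0.1 * rep,
                    }
                )
    ext = pd.DataFrame(
        [
            {"animal_id": "a1", "tissue": "cerebellum", "internal_standard": 5.0, "pellet_weight": 2.0},
            {"animal_id": "a2", "tissue": "cerebellum", "internal_standard": 4.0, "pellet_weight": 2.5},
        ]
    )
    return AbundanceTable(records=pd.DataFrame(rows), extraction_info=ext)


def averaged_group_matrices(metadata, table, tissue):
    """Normalize, average replicates, and split into (wt, tg) wide matrices."""
    norm = preprocess.normalize_table(table)
    avg = preprocess.average_technical_replicates(norm)
    mat = avg.matrix(tissue)
    wt_ids = [r.animal_id for r in metadata if r.status is Status.WILD_TYPE]
    tg_ids = [r.animal_id for r in metadata if r.status is Status.TRANSGENIC]
    return mat.loc[wt_ids], mat.loc[tg_ids]


def planted_pair_config(n_per_group=6, n_pairs=5, loading=0.995, seed=0, m=51):
    """Single-tissue cohort with transgenic-only latent pairs."""
    kwargs = {}
    if n_per_group != 6:
        kwargs = {
            "n_wt": n_per_group,
            "n_tg": n_per_group,
            "sex_plan_wt": ("ram",) * n_per_group,
            "sex_plan_tg": ("ram",) * n_per_group,
        }
    return simulate.SyntheticConfig(
        tissues=("cerebellum",),
        n_metabolites={"cerebellum": m},
        correlation_plan=tuple(
            simulate.PlantedPair("cerebellum", (2 * k, 2 * k + 1), "tg", loading)
            for k in range(n_pairs)
        ),
        seed=seed,
        **kwargs,
    )


# frozen 6-sample vectors whose full and every leave-one-out correlation is
# weak (|r| <= 0.14); constructed numerically, values verified in-test
WEAK_X = np.array([0.10, -1.02, 0.46, 1.51, -0.21, -0.11])
WEAK_Y = np.array([1.92, 0.89, 0.58, 0.97, 0.18, 1.58])

# 5 mildly scattered points plus one high-leverage point at (3, 3): the full
# correlation is 0.99 but removing the leverage point drops it to 0.50
LEVERAGE_X = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 3.0])
LEVERAGE_Y = np.array([0.2, 0.0, 0.3, 0.1, 0.4, 3.0])
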