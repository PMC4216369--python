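import numpy as np
import pandas as pd
import pytest

from mirsmoke import dataio, simdata


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (Table-1-shaped group sizes)."""
    cfg = simdata.SimulationConfig()
    return cfg, *simdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simdata.SimulationConfig(
        seed=5, n_per_group={"CS": 10, "FS": 8, "NS": 9}, n_mirna=120,
        frac_undetectable=0.2, planted_shared=(20, 6), planted_partial=(6, 2),
        planted_specific={"CS": (3, 2), "FS": (2, 1), "NS": (3, 1)},
        smoke_response=simdata.SmokeResponseConfig(
            n_up=4, n_down=2, n_reversible=1, n_irreversible=3),
        penetrance=0.9,  # 8-10 pairs/group: signed-rank needs high recurrence
    )
    return cfg, *simdata.simulate_cohort(cfg)


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[0.0, 0.5], [1.0, 0.2], [5.0, 12.0]],
        index=["mir-a", "mir-b", "mir-c"],
        columns=["s1", "s2"],
    )
    return dataio.ExpressionMatrix(df)


def make_records(n_per_group, with_survival=False, seed=0):
    """Minimal paired metadata for synthetic group-count checks."""
    rng = np.random.default_rng(seed)
    stages = ["I", "I", "II", "III"]
    records = []
    for g, n in n_per_group.items():
        for i in range(n):
            pid = f"{g}{i:03d}"
            stage = stages[i % 4]
            surv = dict(surv_time=None, event=None)
            if with_survival:
                surv = dict(surv_time=float(rng.uniform(1, 60)),
                            event=bool(rng.random() < 0.6))
            for tissue, suffix in (("tumor", "T"), ("normal", "N")):
                records.append(dataio.SampleRecord(
                    sample_id=f"{pid}-{suffix}", patient_id=pid,
                    tissue=tissue, smoking=g, age=60.0, sex="M", stage=stage,
                    ethnicity="Caucasian",
                    pack_years=None if g == "NS" else 30.0,
                    years_quit=5.0 if g == "FS" else None, **surv))
    return records
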