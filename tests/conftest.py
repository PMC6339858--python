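import numpy as np
import pandas as pd
import pytest

from scalefd import CohortSpec, CohortTable, Epoch, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_epoch():
    return Epoch(0.7 * np.arange(1000.0), fs=200.0, label="ramp")


@pytest.fixture(scope="session")
def small_cohort():
    """A small, quick synthetic cohort shared by pipeline-level tests."""
    spec = CohortSpec(
        n_group_a=3, n_group_b=3, n_channels=4, duration_s=15.0, seed=7
    )
    return spec, *gen_cohort(spec)


def make_cohort_table(
    n_a=6, n_b=5, channels=("Fz", "Cz", "Pz"), bands=("fast",),
    seed=0, group_shift=0.0, cov_slope=0.0,
):
    """Cohort table of log-normal-ish D values built directly from normals."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for g, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            sid = f"{g}{i}"
            subj = rng.normal()
            cov = rng.normal()
            meta.append(
                {"subject": sid, "group": g, "covariate": 20.0 + 3.0 * cov}
            )
            for ch in channels:
                for band in bands:
                    d = 1.6 + 0.1 * subj + 0.05 * rng.normal() + cov_slope * cov
                    if g == "B":
                        d += group_shift
                    rows.append(
                        {"subject": sid, "channel": ch, "band": band, "D": d}
                    )
    return CohortTable(data=pd.DataFrame(rows), meta=pd.DataFrame(meta))
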