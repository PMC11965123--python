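import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_frame():
    """Clinical frame of the cohort reconstructed from the published counts."""
    from lefpon.pipeline import clinical_frame, reconstruct_table1_fixture

    return clinical_frame(reconstruct_table1_fixture())


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=240) and its clinical frame."""
    import lefpon as lp
    from lefpon.pipeline import clinical_frame

    cohort = lp.generate_cohort(lp.CohortConfig(n=240, seed=20240101))
    frame = clinical_frame(cohort)
    meth = np.vstack([r.methylation for r in cohort])
    return cohort, frame, meth


@pytest.fixture()
def categories_from(default_cohort):
    """Quartile categories of every CpG in the default cohort."""
    from lefpon.methylation import categorize_cpg
    from lefpon.simulate import CPG_IDS

    _, _, meth = default_cohort
    cats = {}
    cutoffs = {}
    for j, cpg in enumerate(CPG_IDS):
        cats[cpg], cutoffs[cpg] = categorize_cpg(meth[:, j])
    return pd.DataFrame(cats), cutoffs
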