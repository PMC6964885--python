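import numpy as np
import pytest

import partworth as pw


@pytest.fixture(scope="session")
def schema():
    return pw.crohn_schema()


@pytest.fixture(scope="session")
def coding(schema):
    return pw.CodingMap.from_schema(schema)


@pytest.fixture(scope="session")
def small_design(schema):
    """10-version design with the default two warm-up tasks."""
    design = pw.generate_design(schema, n_versions=10, n_tasks=13, n_alts=3, seed=101)
    design.warmups = pw.make_warmups(schema, n=2, seed=102)
    return design


MU_BENEFIT = np.array([0.10, -0.04, 0.05, 0.0, -0.05, 0.03, 0.02, -0.5, -0.4, -0.6])
MU_RISK = np.array([0.04, -0.05, 0.05, 0.0, -0.05, 0.03, 0.02, 0.5, 0.4, 0.6])


@pytest.fixture(scope="session")
def logit_cohort(small_design, coding):
    """40 purely logit respondents from a single-class population."""
    sigma = np.diag(np.full(10, 0.03**2))
    spec = pw.PopulationSpec(40, (pw.ClassSpec(1.0, MU_BENEFIT, sigma),))
    prefs = pw.simulate_population(spec, seed=201)
    choices = pw.simulate_choices(small_design, prefs, coding, seed=202)
    return prefs, choices
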