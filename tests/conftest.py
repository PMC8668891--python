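import numpy as np
import pytest

from triabc import (
    HeterogeneitySubmodel,
    ParameterDraw,
    ScenarioCategory,
    SpeciesTrio,
)


@pytest.fixture(scope="session")
def empirical_trio():
    """The empirical sampling design: 10/13/8 diploid males."""
    return SpeciesTrio()


@pytest.fixture(scope="session")
def small_trio():
    return SpeciesTrio(n_seq_p1=6, n_seq_p2=6, n_seq_p3=4)


def panmictic_draw(n, trio_category=("AM", "SI"), eps=1e-6):
    """A draw that collapses the three populations almost immediately,
    leaving a single constant-size population of N diploids."""
    return ParameterDraw(
        category=ScenarioCategory(*trio_category),
        submodel=HeterogeneitySubmodel(False, False),
        N_P1=n, N_P2=n, N_P3=n,
        N_found_P1=n, N_found_P2=n, N_found_P3=n,
        T_change_P1=0.0, T_change_P2=0.0, T_change_P3=0.0,
        N_anc12=n, N_anc123=n,
        T_split12=eps, T_split123=2 * eps, T_trans12=0.0,
        M12=0.0, M13=0.0, M23=0.0,
    )


def isolation_draw(n, t12, t123, m12=0.0, category=("AM", "SI"),
                   ttrans=None, m13=0.0, m23=0.0):
    """Constant sizes, clean splits, configurable migration."""
    cat = ScenarioCategory(*category)
    if ttrans is None:
        ttrans = t12 if cat.inner_flow == "SC" else 0.0
    return ParameterDraw(
        category=cat,
        submodel=HeterogeneitySubmodel(False, False),
        N_P1=n, N_P2=n, N_P3=n,
        N_found_P1=n, N_found_P2=n, N_found_P3=n,
        T_change_P1=0.0, T_change_P2=0.0, T_change_P3=0.0,
        N_anc12=n, N_anc123=n,
        T_split12=t12, T_split123=t123, T_trans12=ttrans,
        M12=m12, M13=m13, M23=m23,
    )


@pytest.fixture(scope="session")
def reference_table_reduced(empirical_trio):
    """A reduced reference table shared by the inference-level checks.

    32 models x 50 draws (200 datasets per category), 80 theta-mode loci
    per dataset with the empirical length range and sample sizes.  This is
    the expensive shared resource of the suite; everything model-choice
    and parameter-recovery related reuses it.
    """
    from triabc import PriorConfig, enumerate_models
    from triabc.abc_inference import build_reference_table
    from triabc.synthetic_data import EMPIRICAL_SHAPE, make_locus_specs

    rng = np.random.default_rng(20260901)
    specs = make_locus_specs(EMPIRICAL_SHAPE, rng, n_loci=80)
    return build_reference_table(
        enumerate_models(), 50, specs, mode="theta",
        priors=PriorConfig(), trio=empirical_trio, rng=rng,
    )
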