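import warnings

import numpy as np
import pandas as pd
import pytest

from mbcomics import diffexpr, synth

warnings.filterwarnings("ignore", message="negative moment dispersion")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study layout for fast end-to-end checks."""
    return synth.GeneratorConfig(
        n_genes=800, n_mirnas=120, n_lncrnas=120, n_peaks=600, seed=11
    )


@pytest.fixture(scope="session")
def germline_db():
    return synth.build_germline_db(seed=0)


@pytest.fixture(scope="session")
def repertoire_plan(germline_db):
    return synth.RepertoirePlan(germline_db=germline_db)


@pytest.fixture(scope="session")
def default_expression():
    """Full-size expression matrix with the default planted signature."""
    cfg = synth.GeneratorConfig(seed=1)
    cm, truth = synth.generate_expression(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def default_contrasts(default_expression):
    _, cm, _ = default_expression
    return {
        "g": diffexpr.nb_exact_test(cm, "NBC", "IgG"),
        "a": diffexpr.nb_exact_test(cm, "NBC", "IgA"),
        "iso": diffexpr.nb_exact_test(cm, "IgA", "IgG"),
    }


def toy_matrix(counts, subsets, lengths=None, feature_class=None):
    """Helper: CountMatrix from a plain array and subset labels."""
    counts = np.asarray(counts)
    fids = [f"F{i}" for i in range(counts.shape[0])]
    sids = [f"s{i}" for i in range(counts.shape[1])]
    samples = pd.DataFrame({"subset": subsets}, index=sids)
    return diffexpr.CountMatrix(
        counts=pd.DataFrame(counts, index=fids, columns=sids),
        samples=samples,
        lengths=None if lengths is None else pd.Series(lengths, index=fids),
        feature_class=None
        if feature_class is None
        else pd.Series(feature_class, index=fids),
    )
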