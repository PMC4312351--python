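import numpy as np
import pytest

from scglasso import (
    CohortSpec,
    make_cohort,
    multichannel_ess,
    sample_covariance,
    select_lambda,
    weights_for_mode,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cohort40():
    """Default two-group synthetic cohort: 2 x 20 subjects, p=20."""
    return make_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def cohort40_selections(cohort40):
    """BIC-selected networks of every cohort subject under all three
    penalty variants; shared across tests because the lambda searches
    dominate the suite's runtime."""
    out = {}
    for mode in ("GL", "GLa", "GLd"):
        per_subject = []
        for rec in cohort40:
            S = sample_covariance(rec.envelopes, rec.fd.labels)
            W = None if mode == "GL" else weights_for_mode(mode, S, rec.fd)
            n_eff = multichannel_ess(rec.envelopes)
            sel = select_lambda(S, W, n_eff, weight_mode=mode)
            per_subject.append(sel)
        out[mode] = per_subject
    return out


@pytest.fixture(scope="session")
def gld_feature_table(cohort40, cohort40_selections):
    """Feature table of vectorized GLd precisions for the default cohort."""
    from scglasso import FeatureTable, vectorize_precision

    rows, labels = [], None
    for rec, sel in zip(cohort40, cohort40_selections["GLd"]):
        vec, pair_labels = vectorize_precision(sel.final.theta)
        rows.append(vec)
        labels = labels or pair_labels
    y = np.asarray([rec.group for rec in cohort40])
    return FeatureTable(np.asarray(rows), labels, y)
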