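import numpy as np
import pytest

from drtriage import CohortParams, calibrate_classifier, simulate_cohort


@pytest.fixture(scope="session")
def model953():
    """Score model calibrated to AUC 0.953 at the deployed threshold."""
    return calibrate_classifier(0.953, "binormal")


@pytest.fixture(scope="session")
def baseline_cohort(model953):
    """A 2,000-patient single-visit cohort with default rates."""
    params = CohortParams(n_patients=2000, years=[2009], rng_seed=42)
    return simulate_cohort(params, model953)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# -- independent oracles (kept free of the implementations they check) ----

def mann_whitney_auc(pos, neg):
    """Exhaustive concordant-pair count: P(pos > neg) + 0.5 P(tie)."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum())
                 / (pos.size * neg.size))


def cohen_kappa_2x2(a, b, c, d):
    """Unweighted Cohen's kappa from raw 2x2 counts, first principles."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:  # degenerate: all mass in one cell
        return float("nan")
    return (po - pe) / (1 - pe)
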