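import numpy as np
import pytest

import zonelvq as z


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small deterministic cohort (4 normal + 4 suspected) at zero noise."""
    base = z.PhantomSpec(noise_sd=0.0)
    return z.generate_cohort(4, 4, seed=11, base=base)


def pipeline_features(records, threshold=None):
    """Binarize -> zone counts -> features for a list of phantom records."""
    spec = threshold or z.ThresholdSpec()
    X, labels, counts = [], [], []
    for rec in records:
        c = z.partition_and_count(z.binarize(rec.image, spec))
        counts.append(c)
        X.append(z.extract_features(c))
        labels.append(rec.label)
    return np.vstack(X), labels, counts
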