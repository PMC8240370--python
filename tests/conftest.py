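import numpy as np
import pytest

import methylsex as ms


@pytest.fixture(scope="session")
def normal_cohort():
    """A 100F/100M cohort of normal karyotypes, default generator settings."""
    cfg = ms.GeneratorConfig(
        n_samples=200,
        karyotype_proportions={"46,XX": 0.5, "46,XY": 0.5},
        seed=11,
    )
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained(normal_cohort):
    """Model + selection table trained on the normal cohort."""
    return ms.train_sex_model(
        normal_cohort.beta, normal_cohort.sheet, normal_cohort.annotation, seed=11
    )


@pytest.fixture(scope="session")
def model(trained):
    return trained[0]


@pytest.fixture(scope="session")
def mixed_cohort():
    """Default karyotype mix (incl. 45,XO and 47,XXY), 200 samples."""
    return ms.generate_cohort(ms.GeneratorConfig(n_samples=200, seed=77))


@pytest.fixture()
def tiny_beta():
    """4 probes x 3 samples, fully observed, with known chromosomes."""
    values = np.array(
        [
            [0.10, 0.20, 0.30],  # autosome
            [0.50, 0.60, 0.70],  # autosome
            [0.80, 0.15, 0.40],  # X
            [0.30, 0.75, 0.35],  # Y
        ]
    )
    beta = ms.BetaMatrix(["a1", "a2", "x1", "y1"], ["s1", "s2", "s3"], values)
    ann = ms.ProbeAnnotation({"a1": "1", "a2": "chr2", "x1": "chrX", "y1": "y"})
    return beta, ann
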