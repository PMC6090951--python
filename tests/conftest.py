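import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grslife import grs, synthetic
from grslife.data import GenotypeMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def weights():
    return synthetic.default_variant_weights()


@pytest.fixture(scope="session")
def genotypes(weights):
    return synthetic.simulate_genotypes(400, weights, seed=11)


@pytest.fixture(scope="session")
def scores(genotypes, weights):
    aligned, kept, _ = grs.align_weights(genotypes, weights)
    return grs.standardize(grs.compute_wgrs(aligned, kept))


@pytest.fixture(scope="session")
def cohort(scores):
    """A small complete cohort: anthro + truth + LMS + labels + grsz."""
    cfg = synthetic.SimConfig(n_subjects=400, seed=11, missing_rate=0.1)
    labels = synthetic.simulate_trajectory_labels(scores.wgrsz, cfg.classes, 12)
    anthro, truth, lms = synthetic.simulate_longitudinal_anthro(
        scores.wgrsz, labels, cfg, 13
    )
    return {
        "config": cfg,
        "anthro": anthro,
        "truth": truth,
        "lms": lms,
        "labels": labels,
        "grsz": scores.wgrsz,
        "subject_ids": scores.subject_ids,
    }


def make_matrix(dosages, sex=None):
    """GenotypeMatrix from a plain array with generated ids and A/G alleles."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        subject_ids=[f"S{i:03d}" for i in range(n)],
        variant_ids=[f"rs{j}" for j in range(m)],
        dosages=d,
        counted_alleles=["A"] * m,
        other_alleles=["G"] * m,
        sex=sex,
    )
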