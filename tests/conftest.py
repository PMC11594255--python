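import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluidprint as fp

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return fp.default_library()


@pytest.fixture(scope="session")
def urine_cohort(library):
    """A small three-class urine cohort with the demo effect sizes."""
    design = fp.demo_design(
        "urine", {"HEALTHY": 12, "G12.0": 10, "G12.1": 10}, seed=11
    )
    spectra, metadata, table = fp.generate_cohort(design, library)
    return design, spectra, metadata, table


@pytest.fixture(scope="session")
def urine_buckets(urine_cohort):
    _, spectra, metadata, _ = urine_cohort
    table = fp.build_bucket_table(spectra, fp.default_config("urine"))
    return table, [m.class_label for m in metadata]


@pytest.fixture(scope="session")
def null_cohort(library):
    """Zero-effect cohort: all classes drawn from the same distribution."""
    design = fp.CohortDesign(
        biofluid="urine",
        n_per_class={"HEALTHY": 10, "G12.0": 10, "G12.1": 10},
        effect_sizes={},
        seed=23,
    )
    return fp.generate_cohort(design, library)


def rank_h_oracle(groups):
    """Independent brute-force Kruskal-Wallis H (mid-ranks, tie-corrected)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    s = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    offset = 0
    h = 0.0
    for g in groups:
        g = np.asarray(g, float)
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0
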