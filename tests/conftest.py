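import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def doubling_curve():
    """Perfect-doubling assay: slope log10(2) per cycle, intercept 40, LOD 100."""
    from beeqmp.qpcr import StandardCurve

    return StandardCurve(
        target_id="target", slope=-3.3219280948873623, intercept=40.0, lod_copies=100.0,
        rrna_loci=4,
    )


@pytest.fixture
def small_counts():
    """Tiny annotated ASV table exercising exclusion, filtering and collapsing."""
    counts = pd.DataFrame(
        {
            "s1": [50, 10, 9, 5, 100],
            "s2": [30, 20, 0, 5, 80],
            "s3": [20, 30, 0, 0, 60],
        },
        index=["asv_firm5_1", "asv_firm5_2", "asv_rare", "asv_gillia", "asv_chloro"],
    )
    annotations = pd.DataFrame(
        {
            "phylotype": ["lactobacillus_firm5", "lactobacillus_firm5", "serratia",
                          "gilliamella", "plant_chloroplast"],
            "category": ["core", "core", "minor", "core", "excluded"],
            "excluded_reason": ["", "", "", "", "chloroplast"],
            "rrna_loci": [4, 4, 7, 4, 1],
        },
        index=counts.index,
    )
    return counts, annotations
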