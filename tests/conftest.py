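import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from culteval.profiles import SampleMeta, TaxonLineage, TaxonProfile


def make_profile(counts, lineages, samples=None, units="reads"):
    """Build a TaxonProfile from a {feature: lineage-string} map and counts."""
    counts = np.asarray(counts)
    feature_ids = list(lineages)
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return TaxonProfile(
        feature_ids=feature_ids,
        lineages={f: TaxonLineage.from_string(l) for f, l in lineages.items()},
        samples=samples,
        counts=counts,
        units=units,
    )


@pytest.fixture
def toy_profile():
    """3 features (2 sharing a genus), 2 samples."""
    lineages = {
        "F1": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;S_oralis",
        "F2": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;S_mitis",
        "F3": "Bacteria;Fusobacteriota;Fusobacteriia;Fusobacteriales;Fusobacteriaceae;Fusobacterium;F_nucleatum",
    }
    return make_profile([[3, 10], [4, 0], [5, 2]], lineages)


@pytest.fixture
def toy_meta():
    return SampleMeta(
        table=pd.DataFrame(
            {
                "sample_id": ["s0", "s1"],
                "role": ["inoculum", "print"],
                "donor": ["d1", "d1"],
                "medium": ["", "MSPS_029"],
                "atmosphere": ["na", "anaerobic"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """A seeded synthetic study reused by several test modules."""
    from culteval.synthdata import simulate_study

    return simulate_study(n_features=80, n_media=4, seed=42)
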