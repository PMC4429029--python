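import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pairomics import (
    DifferentialRecord,
    PairedOmicsMatrix,
    ProbeAnnotation,
    SimulationConfig,
    generate_dataset,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_matrix(platform, tumor, normal, features=None, pairs=None):
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    features = features or [f"f{i}" for i in range(tumor.shape[0])]
    pairs = pairs or [f"s{j + 1}" for j in range(tumor.shape[1])]
    return PairedOmicsMatrix(
        platform=platform,
        tumor=pd.DataFrame(tumor, index=features, columns=pairs),
        normal=pd.DataFrame(normal, index=features, columns=pairs),
    )


def make_diff(feature_id, mean_diff, significant=True, p=1e-9):
    """Differential record shorthand for gene-level tests."""
    return DifferentialRecord(
        feature_id=feature_id,
        n_complete_pairs=30,
        mean_diff=mean_diff,
        t_stat=10.0 * np.sign(mean_diff),
        p_value=p if significant else 0.5,
        direction=("up" if mean_diff > 0 else "down") if significant else "none",
        significant=significant,
        threshold_used=4.5e-5,
    )


def make_ann(probe_id, platform, gene, chrom="chr1", start=0, end=None):
    return ProbeAnnotation(
        probe_id=probe_id,
        platform=platform,
        chromosome=chrom,
        start=start,
        end=end if end is not None else start + 50,
        gene_symbol=gene,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded synthetic cohort shared by the slower integration tests."""
    cfg = SimulationConfig(n_genes=120, n_pairs=30, seed=2024)
    return cfg, generate_dataset(cfg)
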