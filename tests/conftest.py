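"""Shared fixtures: small synthetic studies and hand-built feature tables."""

import numpy as np
import pandas as pd
import pytest

from metabodcv.synthetic import SimConfig, generate_study
from metabodcv.tables import BLANK, QC_POOL, SAMPLE, FeatureTable


def make_table(features, intensities, samples):
    """Build a FeatureTable from plain dicts/lists.

    ``features``: list of (id, mz, rt, mode); ``samples``: list of
    (id, subject, arm, visit, sample_type, batch, injection_order);
    ``intensities``: 2-D array-like, rows matching features, columns samples.
    """
    feat = pd.DataFrame(
        features, columns=["feature_id", "mz", "rt", "mode"]
    ).set_index("feature_id")
    samp = pd.DataFrame(
        samples,
        columns=["sample_id", "subject", "arm", "visit", "sample_type", "batch", "injection_order"],
    ).set_index("sample_id")
    inten = pd.DataFrame(np.asarray(intensities, float), index=feat.index, columns=samp.index)
    table = FeatureTable(feat, inten, samp)
    table.validate()
    return table


def simple_samples(n_subjects=4, n_blanks=1, n_qc=3, batch=1):
    """One batch: blanks, interleaved QCs, and paired subject samples."""
    rows = []
    inj = 0
    for b in range(n_blanks):
        rows.append((f"BLK{b}", "", "", "", BLANK, batch, inj))
        inj += 1
    for q in range(n_qc - 1):
        rows.append((f"QC{q}", "", "", "", QC_POOL, batch, inj))
        inj += 1
    for s in range(n_subjects):
        arm = "C" if s < n_subjects // 2 else "Ex"
        for visit in ("baseline", "week8"):
            rows.append((f"S{s}_{visit}", f"S{s}", arm, visit, SAMPLE, batch, inj))
            inj += 1
    rows.append((f"QC{n_qc - 1}", "", "", "", QC_POOL, batch, inj))
    return rows


@pytest.fixture(scope="session")
def small_study():
    """A compact clean study (no blank/isotope artifacts) with ground truth."""
    cfg = SimConfig(
        n_subjects_per_arm=20,
        n_features_per_mode=(40, 40),
        n_discriminating=8,
        n_blank_features=0,
        n_isotope_pairs=0,
        rng_seed=42,
    )
    table, clinical, truth = generate_study(cfg)
    return cfg, table, clinical, truth


@pytest.fixture(scope="session")
def artifact_study():
    """A compact study carrying blank-borne and isotope artifact features."""
    cfg = SimConfig(
        n_subjects_per_arm=12,
        n_features_per_mode=(30, 30),
        n_discriminating=6,
        n_blank_features=5,
        n_isotope_pairs=4,
        rng_seed=21,
    )
    table, clinical, truth = generate_study(cfg)
    return cfg, table, clinical, truth
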