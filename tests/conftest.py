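import logging

import numpy as np
import pandas as pd
import pytest

from siggraph import CohortDataset, Signature, SignatureSet

logging.getLogger("siggraph").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


@pytest.fixture
def small_cohort():
    """3 genes x 4 samples, row means already 1."""
    expression = pd.DataFrame(
        {
            "s1": [0.5, 1.0, 2.0],
            "s2": [1.5, 1.0, 0.0],
            "s3": [0.5, 1.0, 1.0],
            "s4": [1.5, 1.0, 1.0],
        },
        index=["gA", "gB", "gC"],
    )
    metadata = pd.DataFrame(
        {
            "diagnosis": ["case", "case", "control", "control"],
            "disease": "scz",
            "disease_class": "PSY",
            "tissue": "brain",
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CohortDataset(cohort_id="toy", expression=expression, metadata=metadata)


def make_signature(cohort_id, rank_k, index_in_rank, gene_exposures, sample_exposures=None):
    genes = [f"g{i}" for i in range(len(gene_exposures))] if not isinstance(
        gene_exposures, pd.Series
    ) else None
    ge = (
        gene_exposures
        if isinstance(gene_exposures, pd.Series)
        else pd.Series(np.asarray(gene_exposures, dtype=float), index=genes)
    )
    if sample_exposures is None:
        sample_exposures = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
    return Signature(
        cohort_id=cohort_id,
        rank_k=rank_k,
        index_in_rank=index_in_rank,
        gene_exposures=ge,
        sample_exposures=sample_exposures,
    )


def make_sigset(cohort_id, exposure_rows, gene_labels, disease="scz",
                disease_class="PSY", tissue="brain"):
    """SignatureSet from a list of exposure vectors over shared gene labels."""
    sigs = []
    for i, row in enumerate(exposure_rows):
        sigs.append(
            Signature(
                cohort_id=cohort_id,
                rank_k=len(exposure_rows),
                index_in_rank=i,
                gene_exposures=pd.Series(np.asarray(row, dtype=float), index=gene_labels),
                sample_exposures=pd.Series([1.0] * 4, index=[f"{cohort_id}_s{j}" for j in range(4)]),
            )
        )
    return SignatureSet(
        cohort_id=cohort_id, disease=disease, disease_class=disease_class,
        tissue=tissue, signatures=sigs,
    )
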