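"""Diagnosis-association filtering of signatures.

Each signature's per-sample exposures (its H row) are regressed on the
case/control label with any available covariates (age, sex, ...) adjusted
for: ``exposure ~ diagnosis + covariates``. The two-sided t-test p-value of
the diagnosis coefficient decides retention at a raw threshold (default
p < 0.05, strict, no multiple-testing correction at this stage — under a null
cohort the retained fraction should therefore sit near alpha, which is the
calibration property the tests check).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .nmf import Signature, SignatureSet

logger = logging.getLogger(__name__)


def _design_matrix(
    diagnosis: pd.Series,
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    """Build the OLS design: intercept + case indicator + dummy-coded covariates.

    Categorical covariates are dummy-coded with the lexicographically first
    level as reference. Covariate columns that are collinear with the columns
    already in the design are dropped (later column loses), with a warning.
    """
    design = pd.DataFrame(
        {
            "const": np.ones(len(diagnosis)),
            "diagnosis": (diagnosis == "case").astype(float).to_numpy(),
        },
        index=diagnosis.index,
    )
    if covariates is None or covariates.shape[1] == 0:
        return design

    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            block = pd.DataFrame({name: col.astype(float)})
        else:
            levels = sorted(col.astype(str).unique())
            block = pd.DataFrame(index=col.index)
            for level in levels[1:]:  # first level is the reference
                block[f"{name}[{level}]"] = (col.astype(str) == level).astype(float)
        for colname in block.columns:
            candidate = pd.concat([design, block[[colname]]], axis=1)
            if np.linalg.matrix_rank(candidate.to_numpy()) > np.linalg.matrix_rank(
                design.to_numpy()
            ):
                design = candidate
            else:
                logger.warning(
                    "dropping collinear covariate column %r from the design", colname
                )
    return design


def associate_signature(
    sample_exposures: pd.Series | np.ndarray,
    diagnosis: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> float:
    """P-value of the diagnosis effect on one signature's sample exposures.

    Fits ``exposure ~ diagnosis + covariates`` by OLS and returns the
    two-sided t-test p-value of the diagnosis coefficient. Degenerate
    (zero-variance) exposures carry no evidence and return p = 1. Samples with
    missing covariate values are dropped (count logged).
    """
    y = pd.Series(np.asarray(sample_exposures, dtype=float))
    diagnosis = pd.Series(np.asarray(diagnosis, dtype=object), index=y.index)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        covariates.index = y.index
        complete = ~covariates.isna().any(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropping %d sample(s) with missing covariates", n_dropped)
            y, diagnosis, covariates = y[complete], diagnosis[complete], covariates[complete]

    for level in ("case", "control"):
        if int((diagnosis == level).sum()) < 2:
            raise ValueError(f"need >= 2 samples with diagnosis {level!r}")

    if float(np.ptp(y.to_numpy())) == 0.0:
        logger.warning("degenerate signature: zero-variance exposures, p set to 1")
        return 1.0

    design = _design_matrix(diagnosis, covariates)
    fit = sm.OLS(y.to_numpy(), design.to_numpy()).fit()
    p = float(fit.pvalues[list(design.columns).index("diagnosis")])
    return 1.0 if not np.isfinite(p) else p


def retain_mask(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Strict-inequality retention: keep p < alpha."""
    return np.asarray(pvalues, dtype=float) < alpha


def filter_signatures(
    sigset: SignatureSet,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    covariate_names: list[str] | None = None,
) -> SignatureSet:
    """Keep the signatures whose exposures associate with diagnosis (p < alpha).

    Every signature in the returned set carries its ``diagnosis_p``. With no
    retained signature the cohort simply contributes no graph nodes (warning,
    not an error).
    """
    if covariate_names:
        missing = [c for c in covariate_names if c not in metadata.columns]
        if missing:
            raise ValueError(f"covariates not in metadata: {missing}")

    retained: list[Signature] = []
    for sig in sigset.signatures:
        samples = sig.sample_exposures.index
        diagnosis = metadata.loc[samples, "diagnosis"]
        covs = metadata.loc[samples, covariate_names] if covariate_names else None
        p = associate_signature(sig.sample_exposures, diagnosis, covs)
        sig.diagnosis_p = p
        if retain_mask(np.array([p]), alpha)[0]:
            retained.append(sig)

    if not retained:
        logger.warning(
            "cohort %s: no diagnosis-associated signature at alpha=%g; "
            "cohort contributes no graph nodes", sigset.cohort_id, alpha,
        )
    return SignatureSet(
        cohort_id=sigset.cohort_id,
        disease=sigset.disease,
        disease_class=sigset.disease_class,
        tissue=sigset.tissue,
        signatures=retained,
        losses=dict(sigset.losses),
    )
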