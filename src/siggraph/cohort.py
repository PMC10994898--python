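"""Cohort expression data: loading, validation and row-mean normalization.

A cohort is one case--control expression study: a nonnegative gene-by-sample
matrix (e.g. fRMA-normalized microarray intensities already summarized to gene
symbols) together with per-sample metadata carrying the diagnosis label, a
lower-case disease code (``scz``, ``t2d``, ``ami`` ...), an upper-case disease
class (``PSY``, ``CVD``, ``T2D``), the tissue of origin and any further
covariates (age, sex, BMI ...).

Expression values are put on a common scale by dividing every gene row by its
mean, so each retained gene has mean 1 across the cohort's samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = ("diagnosis", "disease", "disease_class", "tissue")
DIAGNOSIS_LEVELS = ("case", "control")


class CohortValidationError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class CohortDataset:
    """One cohort's nonnegative expression matrix plus sample metadata.

    Parameters
    ----------
    cohort_id
        Stable identifier for the cohort (e.g. a GEO accession).
    expression
        Genes x samples DataFrame; row index = gene labels, columns = sample
        identifiers. All values must be finite and >= 0.
    metadata
        Sample-indexed DataFrame with at least the columns ``diagnosis``
        (``case``/``control``), ``disease``, ``disease_class`` and ``tissue``.
        Any extra columns are treated as covariates.
    """

    cohort_id: str
    expression: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise CohortValidationError(
                f"cohort {self.cohort_id}: missing required column: {', '.join(missing)}"
            )

        expr_samples = set(map(str, self.expression.columns))
        meta_samples = set(map(str, self.metadata.index))
        if expr_samples != meta_samples:
            only_expr = sorted(expr_samples - meta_samples)
            only_meta = sorted(meta_samples - expr_samples)
            raise CohortValidationError(
                f"cohort {self.cohort_id}: expression and metadata sample sets differ; "
                f"only in expression: {only_expr}; only in metadata: {only_meta}"
            )

        values = self.expression.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"cohort {self.cohort_id}: negative or non-finite expression value "
                f"{values[i, j]!r} at gene {self.expression.index[i]!r}, "
                f"sample {self.expression.columns[j]!r}"
            )

        if self.expression.index.duplicated().any():
            dupes = sorted(set(self.expression.index[self.expression.index.duplicated()]))
            raise CohortValidationError(
                f"cohort {self.cohort_id}: duplicate gene labels: {dupes[:10]}"
            )

        diag = self.metadata["diagnosis"]
        unknown = set(diag.unique()) - set(DIAGNOSIS_LEVELS)
        if unknown:
            raise CohortValidationError(
                f"cohort {self.cohort_id}: diagnosis values must be 'case'/'control', "
                f"found {sorted(unknown)}"
            )
        n_case = int((diag == "case").sum())
        n_control = int((diag == "control").sum())
        if n_case < 2 or n_control < 2:
            raise CohortValidationError(
                f"cohort {self.cohort_id}: need >= 2 cases and >= 2 controls, "
                f"found {n_case} cases / {n_control} controls"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    @property
    def diagnosis(self) -> pd.Series:
        """Diagnosis labels aligned to expression column order."""
        return self.metadata.loc[self.expression.columns, "diagnosis"]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.metadata.columns if c not in REQUIRED_METADATA_COLUMNS]

    def _cohort_level(self, column: str) -> str:
        """Cohort-level value of a metadata column (mode over case samples)."""
        cases = self.metadata.loc[self.metadata["diagnosis"] == "case", column]
        if cases.nunique() > 1:
            logger.warning(
                "cohort %s: multiple %s values among cases; using the most frequent",
                self.cohort_id, column,
            )
        return str(cases.mode().iloc[0])

    @property
    def disease(self) -> str:
        return self._cohort_level("disease")

    @property
    def disease_class(self) -> str:
        return self._cohort_level("disease_class")

    @property
    def tissue(self) -> str:
        return self._cohort_level("tissue")

    def normalized(self, epsilon: float = 1e-12) -> "CohortDataset":
        """Return a copy with row-mean-normalized expression (gene means = 1)."""
        return CohortDataset(
            cohort_id=self.cohort_id,
            expression=rowmean_normalize(self.expression, epsilon=epsilon),
            metadata=self.metadata.copy(),
        )


def rowmean_normalize(expression: pd.DataFrame, epsilon: float = 1e-12) -> pd.DataFrame:
    """Divide each gene row by its mean so every retained row has mean 1.

    Genes whose row mean is <= ``epsilon`` cannot be rescaled and are dropped
    (with a warning). Idempotent and zero-pattern-preserving on retained rows.
    """
    if expression.size == 0:
        raise ValueError("cannot normalize an empty expression matrix")
    means = expression.mean(axis=1)
    keep = means > epsilon
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "rowmean_normalize: dropping %d gene(s) with mean <= %g: %s",
            n_dropped, epsilon, list(expression.index[~keep][:10]),
        )
    retained = expression.loc[keep]
    return retained.div(means[keep], axis=0)


def load_cohort(
    expression_path: str | Path,
    metadata_path: str | Path,
    cohort_id: str,
) -> CohortDataset:
    """Load and validate one cohort from tab-separated files.

    The expression file has gene labels in the first column and sample
    identifiers in the header; the metadata file is sample-indexed with the
    required columns ``diagnosis``, ``disease``, ``disease_class``, ``tissue``.

    Cleaning applied before validation, in order: gene rows containing missing
    values are dropped, then sample columns still containing missing values;
    duplicated gene labels keep the row with the highest mean.
    """
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    expression.index = expression.index.astype(str)
    expression.columns = expression.columns.astype(str)
    metadata.index = metadata.index.astype(str)

    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise CohortValidationError(f"missing required column: {', '.join(missing)}")

    # missing-value policy: drop affected gene rows first, then sample columns
    row_has_na = expression.isna().any(axis=1)
    if row_has_na.any():
        logger.warning(
            "cohort %s: dropping %d gene row(s) with missing values",
            cohort_id, int(row_has_na.sum()),
        )
        expression = expression.loc[~row_has_na]
    col_has_na = expression.isna().any(axis=0)
    if col_has_na.any():
        logger.warning(
            "cohort %s: dropping %d sample column(s) with missing values",
            cohort_id, int(col_has_na.sum()),
        )
        expression = expression.loc[:, ~col_has_na]
        # keep metadata rows for surviving samples only
        metadata = metadata.loc[[s for s in metadata.index if s in set(expression.columns)]]

    if expression.index.duplicated().any():
        means = expression.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        dedup = expression.iloc[order]
        dedup = dedup[~dedup.index.duplicated(keep="first")]
        n_dropped = expression.shape[0] - dedup.shape[0]
        logger.warning(
            "cohort %s: %d duplicate gene label(s); kept highest-mean row each",
            cohort_id, n_dropped,
        )
        expression = dedup.loc[sorted(dedup.index)]

    return CohortDataset(cohort_id=cohort_id, expression=expression, metadata=metadata)


def write_cohort(
    cohort: CohortDataset,
    expression_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a cohort back to the tab-separated on-disk layout."""
    cohort.expression.to_csv(expression_path, sep="\t", float_format="%.17g")
    cohort.metadata.to_csv(metadata_path, sep="\t")


def load_manifest(manifest_path: str | Path) -> list[CohortDataset]:
    """Load all cohorts listed in a manifest (YAML list or TSV table).

    Each entry needs ``cohort_id``, ``expression_path`` and ``metadata_path``;
    relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.suffix.lower() in {".yaml", ".yml"}:
        with open(manifest_path) as fh:
            entries = yaml.safe_load(fh)
        if isinstance(entries, dict):
            entries = entries.get("cohorts", [])
    else:
        entries = pd.read_csv(manifest_path, sep="\t").to_dict("records")

    cohorts = []
    base = manifest_path.parent
    for entry in entries:
        expr = Path(entry["expression_path"])
        meta = Path(entry["metadata_path"])
        cohorts.append(
            load_cohort(
                base / expr if not expr.is_absolute() else expr,
                base / meta if not meta.is_absolute() else meta,
                str(entry["cohort_id"]),
            )
        )
    return cohorts
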