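"""Synthetic multi-cohort expression data with planted, partially shared factors.

The generator emulates the structure the signature-graph framework assumes:
several case--control cohorts, each a nonnegative genes x samples matrix built
as a sum of rank-one latent factors (a nonnegative gene-loading vector times a
nonnegative per-sample exposure vector) over a positive per-gene baseline,
degraded by multiplicative lognormal noise. Factors may be active only in
cases (disease programs), only in controls, or in all samples (tissue/batch
programs), and the same factor can be planted in several cohorts — those
cohort pairs are the ground-truth edges the pipeline should recover.

Gene loadings of a factor are large on its designated signature genes and
small (about 1% of the signature scale) elsewhere, so recovering the top
genes is a genuine inference problem rather than a support read-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDataset, write_cohort

_OFF_SIGNATURE_FRACTION = 0.01  # off-signature loading scale relative to signature genes


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    disease: str
    disease_class: str
    tissue: str
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class FactorSpec:
    """A planted latent factor.

    ``active_in`` lists (cohort_id, group) pairs with group one of
    'case', 'control', 'all'; the factor's sample exposures are nonzero only
    for samples of that group in that cohort.
    """

    factor_id: str
    signature_genes: tuple[int, ...]
    active_in: tuple[tuple[str, str], ...]
    exposure_scale: float = 10.0


@dataclass(frozen=True)
class CovariateSpec:
    """An extra metadata column: 'uniform' (low/high) or 'bernoulli' (levels)."""

    name: str
    kind: str = "uniform"
    low: float = 20.0
    high: float = 80.0
    levels: tuple[str, str] = ("F", "M")
    # optional coupling: covariate = draw + strength * factor sample-exposure
    couple_to_factor: str | None = None
    couple_strength: float = 0.0


@dataclass
class SyntheticDesign:
    n_genes: int
    cohorts: list[CohortSpec]
    factors: list[FactorSpec]
    noise_scale: float = 0.5
    background_range: tuple[float, float] = (0.5, 1.5)
    covariates: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = {c.cohort_id for c in self.cohorts}
        if len(ids) != len(self.cohorts):
            raise ValueError("duplicate cohort_id in design")
        for c in self.cohorts:
            if c.n_cases < 1 or c.n_controls < 1:
                raise ValueError(
                    f"cohort {c.cohort_id}: needs >= 1 case and >= 1 control"
                )
        for f in self.factors:
            if not f.signature_genes:
                raise ValueError(f"factor {f.factor_id}: empty signature gene set")
            if max(f.signature_genes) >= self.n_genes or min(f.signature_genes) < 0:
                raise ValueError(
                    f"factor {f.factor_id}: signature gene index out of range"
                )
            for cid, group in f.active_in:
                if cid not in ids:
                    raise ValueError(
                        f"factor {f.factor_id}: unknown cohort {cid!r} in active_in"
                    )
                if group not in ("case", "control", "all"):
                    raise ValueError(
                        f"factor {f.factor_id}: group must be case/control/all, got {group!r}"
                    )


@dataclass
class GroundTruth:
    """What was planted: per-cohort true factor matrices and expected edges."""

    gene_loadings: dict[str, pd.DataFrame]  # cohort_id -> genes x factors
    sample_exposures: dict[str, pd.DataFrame]  # cohort_id -> factors x samples
    signature_gene_sets: dict[str, frozenset[str]]  # factor_id -> gene labels
    expected_edges: list[tuple[tuple[str, str], tuple[str, str]]]  # ((cohort, factor), (cohort, factor))

    def to_json_dict(self) -> dict:
        return {
            "signature_gene_sets": {
                f: sorted(g) for f, g in self.signature_gene_sets.items()
            },
            "expected_edges": [[list(a), list(b)] for a, b in self.expected_edges],
        }


def _gene_labels(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def generate(design: SyntheticDesign) -> tuple[list[CohortDataset], GroundTruth]:
    """Generate all cohorts of a design plus the planted ground truth.

    Deterministic: identical designs (including the seed) give bit-identical
    output. Expression is built per cohort as
    ``background + sum_f w_f h_f^T`` then multiplied by lognormal noise
    ``exp(noise_scale * Z)`` and clipped at zero.
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_labels(design.n_genes)
    gene_index = pd.Index(genes)

    cohorts: list[CohortDataset] = []
    gene_loadings: dict[str, pd.DataFrame] = {}
    sample_exposures: dict[str, pd.DataFrame] = {}

    for spec in design.cohorts:
        n = spec.n_cases + spec.n_controls
        samples = [f"{spec.cohort_id}_s{i:03d}" for i in range(n)]
        diagnosis = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)

        active = [f for f in design.factors if any(c == spec.cohort_id for c, _ in f.active_in)]
        W = np.zeros((design.n_genes, len(active)))
        H = np.zeros((len(active), n))
        for fi, f in enumerate(active):
            sig = np.array(f.signature_genes)
            w = _OFF_SIGNATURE_FRACTION * f.exposure_scale * rng.uniform(0.0, 1.0, design.n_genes)
            w[sig] = f.exposure_scale * rng.uniform(0.5, 1.5, sig.size)
            groups = {g for c, g in f.active_in if c == spec.cohort_id}
            mask = np.zeros(n, dtype=bool)
            if "all" in groups:
                mask[:] = True
            if "case" in groups:
                mask |= diagnosis == "case"
            if "control" in groups:
                mask |= diagnosis == "control"
            h = np.zeros(n)
            h[mask] = rng.uniform(0.5, 1.5, int(mask.sum()))
            W[:, fi] = w
            H[fi, :] = h

        background = rng.uniform(*design.background_range, design.n_genes)
        X = background[:, None] + W @ H
        if design.noise_scale > 0:
            X = X * np.exp(rng.normal(0.0, design.noise_scale, X.shape))
        X = np.clip(X, 0.0, None)

        metadata = pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "disease": spec.disease,
                "disease_class": spec.disease_class,
                "tissue": spec.tissue,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        for cov in design.covariates:
            if cov.kind == "uniform":
                values = rng.uniform(cov.low, cov.high, n)
                if cov.couple_to_factor is not None:
                    fids = [f.factor_id for f in active]
                    if cov.couple_to_factor in fids:
                        values = values + cov.couple_strength * H[fids.index(cov.couple_to_factor)]
                metadata[cov.name] = np.round(values, 3)
            elif cov.kind == "bernoulli":
                metadata[cov.name] = rng.choice(list(cov.levels), n)
            else:
                raise ValueError(f"unknown covariate kind {cov.kind!r}")

        expression = pd.DataFrame(X, index=gene_index, columns=samples)
        expression.index.name = "gene"
        cohorts.append(
            CohortDataset(cohort_id=spec.cohort_id, expression=expression, metadata=metadata)
        )
        gene_loadings[spec.cohort_id] = pd.DataFrame(
            W, index=gene_index, columns=[f.factor_id for f in active]
        )
        sample_exposures[spec.cohort_id] = pd.DataFrame(
            H, index=[f.factor_id for f in active], columns=samples
        )

    signature_gene_sets = {
        f.factor_id: frozenset(genes[i] for i in f.signature_genes)
        for f in design.factors
    }
    expected_edges = []
    for f in design.factors:
        cohort_ids = sorted({c for c, _ in f.active_in})
        for a, b in combinations(cohort_ids, 2):
            expected_edges.append(((a, f.factor_id), (b, f.factor_id)))

    truth = GroundTruth(
        gene_loadings=gene_loadings,
        sample_exposures=sample_exposures,
        signature_gene_sets=signature_gene_sets,
        expected_edges=expected_edges,
    )
    return cohorts, truth


# ---------------------------------------------------------------------------
# Standard study designs


def comorbidity_design(
    seed: int = 0,
    n_genes: int = 2000,
    n_cases: int = 20,
    n_controls: int = 20,
    n_signature_genes: int = 150,
    exposure_scale: float = 10.0,
    noise_scale: float = 0.5,
    shared_factor: bool = True,
    private_case_factors: bool = True,
    with_covariates: bool = True,
) -> SyntheticDesign:
    """Four-cohort comorbidity benchmark: two diseases, two tissues each.

    Two schizophrenia-like cohorts (class PSY) and two diabetes-like cohorts
    (class T2D). When ``shared_factor`` is set, one case-active factor of
    ``n_signature_genes`` genes is planted in the cases of one PSY and one
    T2D cohort — the inter-class comorbid edge the pipeline should recover.
    Each cohort additionally gets a private case-active factor (its own
    disease program) and an always-on tissue factor, on disjoint gene blocks.
    """
    cohorts = [
        CohortSpec("scz_brain", "scz", "PSY", "brain", n_cases, n_controls),
        CohortSpec("scz_blood", "scz", "PSY", "blood", n_cases, n_controls),
        CohortSpec("t2d_islet", "t2d", "T2D", "islet", n_cases, n_controls),
        CohortSpec("t2d_liver", "t2d", "T2D", "liver", n_cases, n_controls),
    ]
    m = n_signature_genes
    n_blocks = 1 + 2 * len(cohorts)
    if n_blocks * m > n_genes:
        raise ValueError(
            f"need n_genes >= {n_blocks * m} for disjoint {m}-gene factor blocks"
        )
    block = iter(range(n_blocks))

    def genes_of(b: int) -> tuple[int, ...]:
        return tuple(range(b * m, (b + 1) * m))

    factors: list[FactorSpec] = []
    if shared_factor:
        factors.append(
            FactorSpec(
                "comorbid",
                genes_of(next(block)),
                (("scz_brain", "case"), ("t2d_islet", "case")),
                exposure_scale,
            )
        )
    else:
        next(block)
    for spec in cohorts:
        b_private, b_tissue = next(block), next(block)
        if private_case_factors:
            factors.append(
                FactorSpec(
                    f"{spec.cohort_id}_disease",
                    genes_of(b_private),
                    ((spec.cohort_id, "case"),),
                    exposure_scale,
                )
            )
        factors.append(
            FactorSpec(
                f"{spec.cohort_id}_tissue",
                genes_of(b_tissue),
                ((spec.cohort_id, "all"),),
                exposure_scale,
            )
        )

    covariates = (
        [
            CovariateSpec("age", kind="uniform", low=20, high=80),
            CovariateSpec("sex", kind="bernoulli"),
        ]
        if with_covariates
        else []
    )
    return SyntheticDesign(
        n_genes=n_genes,
        cohorts=cohorts,
        factors=factors,
        noise_scale=noise_scale,
        covariates=covariates,
        seed=seed,
    )


def null_design(
    seed: int = 0,
    n_genes: int = 2000,
    n_cases: int = 20,
    n_controls: int = 20,
    n_signature_genes: int = 150,
    exposure_scale: float = 10.0,
    noise_scale: float = 0.5,
    with_covariates: bool = True,
) -> SyntheticDesign:
    """Null benchmark: same four cohorts, but no diagnosis-linked factor.

    Every cohort carries only an always-on tissue factor on its own gene
    block, so no signature is truly diagnosis-associated and no cross-cohort
    factor is shared — diagnosis-filter retention should sit near alpha and
    permutation testing should remove most chance edges.
    """
    design = comorbidity_design(
        seed=seed,
        n_genes=n_genes,
        n_cases=n_cases,
        n_controls=n_controls,
        n_signature_genes=n_signature_genes,
        exposure_scale=exposure_scale,
        noise_scale=noise_scale,
        shared_factor=False,
        private_case_factors=False,
        with_covariates=with_covariates,
    )
    return design


def write_design_outputs(
    cohorts: list[CohortDataset], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write per-cohort expression/metadata TSVs plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cohort in cohorts:
        write_cohort(
            cohort,
            out / f"{cohort.cohort_id}_expression.tsv",
            out / f"{cohort.cohort_id}_metadata.tsv",
        )
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    rows = [
        {
            "cohort_id": c.cohort_id,
            "expression_path": f"{c.cohort_id}_expression.tsv",
            "metadata_path": f"{c.cohort_id}_metadata.tsv",
        }
        for c in cohorts
    ]
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
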