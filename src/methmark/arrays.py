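"""Beta-value handling for Infinium-style methylation arrays.

A *beta value* is the methylation fraction of a CpG probe: the methylated
signal intensity divided by the total (methylated + unmethylated) signal,
ranging from 0 (unmethylated) to 1 (fully methylated).  This module houses
the probe-level container, probe-to-gene aggregation, the tumor-minus-normal
group contrast (ΔAvg_β), and the array-based hypermethylation call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeBetaMatrix",
    "GeneMethylationSummary",
    "GeneNotCoveredError",
    "beta_from_intensities",
    "aggregate_gene_beta",
    "gene_beta_matrix",
    "delta_avg_beta",
    "call_hypermethylated_beta",
]

#: Sample roles recognised in sample metadata.
ROLES = ("tumor", "adjacent_normal", "normal_panel")


class GeneNotCoveredError(KeyError):
    """Raised when a gene has no annotated probe passing the region filter."""


@dataclass
class ProbeBetaMatrix:
    """Probes-by-samples beta matrix with probe and sample annotation.

    Parameters
    ----------
    beta
        DataFrame of methylation fractions, probes as rows, samples as
        columns.  Missing values allowed (NaN).
    probes
        Probe annotation indexed by probe id, with columns ``gene`` and
        ``region`` (e.g. ``promoter``, ``exon1``, ``body``).
    samples
        Sample metadata indexed by sample id, with columns ``role``
        (tumor / adjacent_normal / normal_panel), ``pair_id``, ``response``
        (CR / PD / none) and ``tissue``.
    """

    beta: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.probes.index):
            self.probes = self.probes.loc[self.beta.index]
        if not self.beta.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.beta.columns]
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return sorted(self.probes["gene"].unique())

    def sample_ids(self, role: str | None = None) -> pd.Index:
        if role is None:
            return self.samples.index
        return self.samples.index[self.samples["role"] == role]

    def subset_samples(self, sample_ids) -> "ProbeBetaMatrix":
        sample_ids = pd.Index(sample_ids)
        return ProbeBetaMatrix(
            self.beta.loc[:, sample_ids], self.probes, self.samples.loc[sample_ids]
        )


@dataclass
class GeneMethylationSummary:
    """Gene-level group means and their difference (ΔAvg_β = tumor − normal)."""

    gene: str
    mean_tumor: float
    mean_normal: float
    delta_avg_beta: float
    n_probes: int = 0


def beta_from_intensities(methylated, unmethylated):
    """Beta value from methylated / unmethylated signal intensities.

    beta = M / (M + U).  Both signals zero yields a missing value (NaN) and
    a warning; negative intensities are rejected.  Accepts scalars or
    arrays (vectorised).
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("signal intensities must be nonnegative")
    total = m + u
    zero = total == 0
    if np.any(zero):
        warnings.warn("zero total intensity: beta set to missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero, np.nan, m / np.where(zero, np.nan, total))
    if beta.ndim == 0:
        return float(beta)
    return beta


def _probe_mask(matrix: ProbeBetaMatrix, gene: str, region_filter=None) -> pd.Index:
    ann = matrix.probes
    mask = ann["gene"] == gene
    if region_filter is not None:
        regions = [region_filter] if isinstance(region_filter, str) else list(region_filter)
        mask &= ann["region"].isin(regions)
    idx = ann.index[mask]
    if len(idx) == 0:
        raise GeneNotCoveredError(f"gene {gene!r} has no probe passing the region filter")
    return idx


def aggregate_gene_beta(
    matrix: ProbeBetaMatrix,
    gene: str,
    region_filter=None,
    sample_subset=None,
    min_probes: int = 1,
) -> pd.Series:
    """Per-sample gene-level beta: unweighted mean of non-missing probe betas.

    Returns a Series indexed by sample id; the number of probes used per
    sample is attached as ``result.attrs["n_probes_used"]``.  Samples where
    fewer than ``min_probes`` probes are non-missing get NaN.
    """
    idx = _probe_mask(matrix, gene, region_filter)
    block = matrix.beta.loc[idx]
    if sample_subset is not None:
        block = block.loc[:, pd.Index(sample_subset)]
    used = block.notna().sum(axis=0)
    means = block.mean(axis=0, skipna=True)
    means[used < min_probes] = np.nan
    means.attrs["n_probes_used"] = used
    means.name = gene
    return means


def gene_beta_matrix(
    matrix: ProbeBetaMatrix, region_filter=None, sample_subset=None
) -> pd.DataFrame:
    """Genes-by-samples matrix of gene-level betas (probe means).

    Vectorised equivalent of calling :func:`aggregate_gene_beta` per gene.
    """
    ann = matrix.probes
    block = matrix.beta
    if region_filter is not None:
        regions = [region_filter] if isinstance(region_filter, str) else list(region_filter)
        keep = ann["region"].isin(regions)
        ann = ann.loc[keep]
        block = block.loc[ann.index]
    if sample_subset is not None:
        block = block.loc[:, pd.Index(sample_subset)]
    return block.groupby(ann["gene"]).mean()


def delta_avg_beta(
    matrix: ProbeBetaMatrix, gene: str, region_filter=None
) -> GeneMethylationSummary:
    """ΔAvg_β for one gene: mean beta over tumors minus mean over normals.

    Group means are unpaired (all tumor samples vs all adjacent-normal
    samples), matching a cohort-average contrast.
    """
    tumors = matrix.sample_ids("tumor")
    normals = matrix.sample_ids("adjacent_normal")
    if len(tumors) == 0 or len(normals) == 0:
        raise ValueError("delta_avg_beta needs at least one tumor and one normal sample")
    per_sample = aggregate_gene_beta(matrix, gene, region_filter)
    mean_t = float(per_sample.loc[tumors].mean())
    mean_n = float(per_sample.loc[normals].mean())
    n_probes = len(_probe_mask(matrix, gene, region_filter))
    return GeneMethylationSummary(gene, mean_t, mean_n, mean_t - mean_n, n_probes)


def call_hypermethylated_beta(tumor_beta, cutoff: float = 0.25):
    """Array-based hypermethylation call: True iff beta strictly exceeds cutoff.

    A beta of exactly the cutoff is *not* hypermethylated ("higher than"
    is strict).  Missing beta yields a missing (NaN) call.
    """
    arr = np.asarray(tumor_beta, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr > cutoff).astype(float))
    if out.ndim == 0:
        val = float(out)
        return val if np.isnan(val) else bool(val)
    return out
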