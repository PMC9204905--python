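"""Five-criterion screening funnel for silenced hypermethylated biomarker genes.

A candidate gene must be (1) hypermethylated in the discovery cohort
(ΔAvg_β > 0.4), (2) hypermethylated in an independent replication cohort at
the same cutoff, (3) among the top-k genes most methylated in poor
responders (PD) relative to complete responders (CR), (4) essentially
unmethylated across a multi-tissue normal panel, and (5) expressed at half
or less in tumors relative to paired normals.  The final candidate list is
the intersection of the five criterion sets, ordered by response rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import ProbeBetaMatrix, gene_beta_matrix

__all__ = [
    "FunnelConfig",
    "FunnelInputs",
    "FunnelReport",
    "criterion_discovery_hypermethylation",
    "criterion_replication_hypermethylation",
    "criterion_response_topk",
    "criterion_normal_low",
    "criterion_expression_halved",
    "run_funnel",
]

CRITERIA = (
    "discovery_hypermethylation",
    "replication_hypermethylation",
    "response_topk",
    "normal_low",
    "expression_halved",
)


@dataclass(frozen=True)
class FunnelConfig:
    delta_beta_cutoff: float = 0.4
    top_k_response: int = 20
    normal_panel_max_beta: float = 0.1
    expression_ratio_cutoff: float = 0.5
    expression_inclusive: bool = True
    region_filter: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_beta_cutoff <= 1.0:
            raise ValueError("delta_beta_cutoff must lie in [0, 1]")
        if self.top_k_response < 1:
            raise ValueError("top_k_response must be at least 1")
        if not 0.0 <= self.normal_panel_max_beta <= 1.0:
            raise ValueError("normal_panel_max_beta must lie in [0, 1]")
        if self.expression_ratio_cutoff < 0:
            raise ValueError("expression_ratio_cutoff must be nonnegative")


@dataclass
class FunnelInputs:
    """The five cohorts the funnel consumes."""

    discovery: ProbeBetaMatrix
    replication: ProbeBetaMatrix
    response: ProbeBetaMatrix          # tumors labeled CR / PD
    normal_panel: ProbeBetaMatrix
    expression_tumor: pd.DataFrame     # genes x tumor samples
    expression_normal: pd.DataFrame    # genes x paired-normal samples


@dataclass
class FunnelReport:
    criterion_sets: dict
    counts: dict
    final_genes: list
    evidence: pd.DataFrame
    errors: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors


def _cohort_delta(matrix: ProbeBetaMatrix, region_filter=None) -> pd.Series:
    tumors = matrix.sample_ids("tumor")
    normals = matrix.sample_ids("adjacent_normal")
    if len(tumors) == 0 or len(normals) == 0:
        raise ValueError("cohort must contain tumor and adjacent-normal samples")
    gb = gene_beta_matrix(matrix, region_filter)
    return gb[tumors].mean(axis=1) - gb[normals].mean(axis=1)


def criterion_discovery_hypermethylation(
    cohort: ProbeBetaMatrix, cutoff: float = 0.4, region_filter=None
) -> set:
    """Genes hypermethylated in a paired cohort: ΔAvg_β strictly above cutoff."""
    delta = _cohort_delta(cohort, region_filter)
    return set(delta.index[delta > cutoff])


#: Same rule applied to the independent replication cohort.
criterion_replication_hypermethylation = criterion_discovery_hypermethylation


def criterion_response_topk(
    pd_samples: pd.DataFrame, cr_samples: pd.DataFrame, k: int = 20
) -> list:
    """Top-k genes by mean(PD) - mean(CR) gene-level beta, descending.

    Inputs are genes-by-samples matrices for the two response groups.
    Ties are broken lexicographically by gene identifier.  Returns the
    ordered top-k gene list.
    """
    if pd_samples.shape[1] == 0 or cr_samples.shape[1] == 0:
        raise ValueError("both response groups must be nonempty")
    if k > pd_samples.shape[0]:
        raise ValueError("k exceeds the number of genes")
    diff = pd_samples.mean(axis=1) - cr_samples.mean(axis=1)
    # deterministic ordering: descending difference, then gene id
    ranked = sorted(diff.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:k]]


def criterion_normal_low(panel: ProbeBetaMatrix, max_beta: float = 0.1) -> set:
    """Genes near-unmethylated in *every* tissue type of the normal panel.

    A gene qualifies iff its mean beta is strictly below ``max_beta`` in
    each tissue type separately (one elevated tissue disqualifies it).
    """
    if len(panel.samples) == 0:
        raise ValueError("normal panel is empty")
    gb = gene_beta_matrix(panel)
    tissue_means = gb.T.groupby(panel.samples["tissue"]).mean().T
    ok = (tissue_means < max_beta).all(axis=1)
    return set(ok.index[ok])


def criterion_expression_halved(
    expression_tumor: pd.DataFrame,
    expression_normal: pd.DataFrame,
    ratio_cutoff: float = 0.5,
    inclusive: bool = True,
) -> set:
    """Genes whose mean tumor expression is at most half the paired-normal mean.

    Genes with a zero normal mean are flagged (ratio undefined) and
    excluded.
    """
    if expression_tumor.shape[1] == 0 or expression_normal.shape[1] == 0:
        raise ValueError("paired tumor and normal expression required")
    t = expression_tumor.mean(axis=1)
    n = expression_normal.mean(axis=1)
    valid = n > 0
    ratio = t[valid] / n[valid]
    hit = ratio <= ratio_cutoff if inclusive else ratio < ratio_cutoff
    return set(ratio.index[hit])


def run_funnel(config: FunnelConfig, inputs: FunnelInputs) -> FunnelReport:
    """Apply all five criteria and intersect, with per-stage bookkeeping.

    Each criterion is evaluated independently; a criterion that raises is
    recorded under ``errors`` and the report is returned partial (its set
    empty, the final intersection computed over the criteria that ran).
    The final list is ordered by response rank.
    """
    sets: dict = {}
    errors: dict = {}

    response_rank: list = []
    steps = {
        "discovery_hypermethylation": lambda: criterion_discovery_hypermethylation(
            inputs.discovery, config.delta_beta_cutoff, config.region_filter
        ),
        "replication_hypermethylation": lambda: criterion_replication_hypermethylation(
            inputs.replication, config.delta_beta_cutoff, config.region_filter
        ),
    }
    for name, step in steps.items():
        try:
            sets[name] = step()
        except Exception as exc:
            errors[name] = str(exc)
            sets[name] = set()

    try:
        resp_gb = gene_beta_matrix(inputs.response, config.region_filter)
        pd_ids = inputs.response.samples.index[inputs.response.samples["response"] == "PD"]
        cr_ids = inputs.response.samples.index[inputs.response.samples["response"] == "CR"]
        response_rank = criterion_response_topk(
            resp_gb[pd_ids], resp_gb[cr_ids], config.top_k_response
        )
        sets["response_topk"] = set(response_rank)
    except Exception as exc:
        errors["response_topk"] = str(exc)
        sets["response_topk"] = set()

    try:
        sets["normal_low"] = criterion_normal_low(
            inputs.normal_panel, config.normal_panel_max_beta
        )
    except Exception as exc:
        errors["normal_low"] = str(exc)
        sets["normal_low"] = set()

    try:
        sets["expression_halved"] = criterion_expression_halved(
            inputs.expression_tumor,
            inputs.expression_normal,
            config.expression_ratio_cutoff,
            config.expression_inclusive,
        )
    except Exception as exc:
        errors["expression_halved"] = str(exc)
        sets["expression_halved"] = set()

    ran = [name for name in CRITERIA if name not in errors]
    final: set = set.intersection(*(sets[name] for name in ran)) if ran else set()
    rank_of = {g: i for i, g in enumerate(response_rank)}
    final_ordered = sorted(final, key=lambda g: (rank_of.get(g, len(rank_of)), g))

    evidence = _evidence_table(config, inputs, sets, final_ordered, errors)
    counts = {name: len(sets[name]) for name in CRITERIA}
    counts["final"] = len(final_ordered)
    return FunnelReport(
        criterion_sets=sets,
        counts=counts,
        final_genes=final_ordered,
        evidence=evidence,
        errors=errors,
    )


def _evidence_table(config, inputs, sets, final_genes, errors) -> pd.DataFrame:
    """Per-gene evidence for the final candidates (best effort on partial runs)."""
    if not final_genes:
        return pd.DataFrame(
            columns=[
                "gene", "delta_beta_discovery", "delta_beta_replication",
                "response_rank", "normal_panel_mean_beta", "expression_ratio",
            ]
        ).set_index("gene")
    rows = {}
    try:
        rows["delta_beta_discovery"] = _cohort_delta(inputs.discovery, config.region_filter)
    except Exception:
        pass
    try:
        rows["delta_beta_replication"] = _cohort_delta(inputs.replication, config.region_filter)
    except Exception:
        pass
    try:
        gb = gene_beta_matrix(inputs.response, config.region_filter)
        pd_ids = inputs.response.samples.index[inputs.response.samples["response"] == "PD"]
        cr_ids = inputs.response.samples.index[inputs.response.samples["response"] == "CR"]
        diff = gb[pd_ids].mean(axis=1) - gb[cr_ids].mean(axis=1)
        ranked = sorted(diff.items(), key=lambda kv: (-kv[1], kv[0]))
        rows["response_rank"] = pd.Series(
            {g: i + 1 for i, (g, _) in enumerate(ranked)}, dtype=float
        )
    except Exception:
        pass
    try:
        rows["normal_panel_mean_beta"] = gene_beta_matrix(inputs.normal_panel).mean(axis=1)
    except Exception:
        pass
    try:
        t = inputs.expression_tumor.mean(axis=1)
        n = inputs.expression_normal.mean(axis=1)
        rows["expression_ratio"] = t / n.where(n > 0)
    except Exception:
        pass
    ev = pd.DataFrame(rows).reindex(final_genes)
    ev.index.name = "gene"
    return ev
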