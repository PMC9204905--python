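"""Five-criterion screening funnel, including a brute-force oracle check."""

import numpy as np
import pandas as pd
import pytest

from methmark.arrays import ProbeBetaMatrix, gene_beta_matrix
from methmark.funnel import (
    FunnelConfig,
    FunnelInputs,
    criterion_discovery_hypermethylation,
    criterion_expression_halved,
    criterion_normal_low,
    criterion_response_topk,
    run_funnel,
)
from methmark.synthetic import (
    CohortConfig,
    simulate_beta_cohort,
    simulate_expression,
    simulate_normal_panel,
    simulate_response_cohort,
)


def _paired_matrix(gene_betas: dict, n_pairs=2, tumor_offset=None):
    """Build a tiny paired cohort with per-gene (tumor, normal) betas."""
    genes = sorted(gene_betas)
    probes = pd.DataFrame(
        {"gene": genes, "region": "promoter"},
        index=pd.Index([f"{g}_p1" for g in genes], name="probe_id"),
    )
    tumor_ids = [f"T{i}" for i in range(1, n_pairs + 1)]
    normal_ids = [f"N{i}" for i in range(1, n_pairs + 1)]
    beta = pd.DataFrame(
        {**{t: [gene_betas[g][0] for g in genes] for t in tumor_ids},
         **{n: [gene_betas[g][1] for g in genes] for n in normal_ids}},
        index=probes.index,
    )
    samples = pd.DataFrame(
        {"role": ["tumor"] * n_pairs + ["adjacent_normal"] * n_pairs,
         "pair_id": [f"P{i}" for i in range(1, n_pairs + 1)] * 2,
         "response": "none", "tissue": "breast"},
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    return ProbeBetaMatrix(beta, probes, samples)


class TestHypermethylationCriterion:
    def test_above_cutoff_included(self):
        m = _paired_matrix({"GA": (0.55, 0.10)})  # delta 0.45
        assert criterion_discovery_hypermethylation(m, 0.4) == {"GA"}

    def test_boundary_excluded_strict(self):
        m = _paired_matrix({"GA": (0.50, 0.10)})  # delta exactly 0.40
        assert criterion_discovery_hypermethylation(m, 0.4) == set()

    def test_planted_cohort_recovered(self):
        cfg = CohortConfig(n_pairs=20, n_genes=1000, delta_beta_effect=0.5,
                           noise_sd=0.05, seed=11)
        hits = criterion_discovery_hypermethylation(simulate_beta_cohort(cfg), 0.4)
        planted = set(cfg.planted())
        assert hits >= planted
        false_rate = len(hits - planted) / (cfg.n_genes - len(planted))
        assert false_rate < 0.01


class TestResponseTopK:
    def _frames(self, diffs):
        genes = [f"g{i}" for i in range(1, len(diffs) + 1)]
        pd_df = pd.DataFrame({"s1": [0.1 + d for d in diffs]}, index=genes)
        cr_df = pd.DataFrame({"s1": [0.1] * len(diffs), "s2": [0.1] * len(diffs)},
                             index=genes)
        return pd_df, cr_df

    def test_sorts_by_group_mean_difference(self):
        pd_df, cr_df = self._frames([0.5, 0.1, 0.3])
        assert criterion_response_topk(pd_df, cr_df, 2) == ["g1", "g3"]

    def test_ties_broken_lexicographically(self):
        pd_df, cr_df = self._frames([0.2, 0.2, 0.2])
        assert criterion_response_topk(pd_df, cr_df, 2) == ["g1", "g2"]

    def test_k_larger_than_genes_rejected(self):
        pd_df, cr_df = self._frames([0.2])
        with pytest.raises(ValueError):
            criterion_response_topk(pd_df, cr_df, 5)

    def test_planted_response_gene_usually_in_top20(self):
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            cfg = CohortConfig(n_pairs=2, n_genes=1000, noise_sd=0.05,
                               planted_genes=("G0500",), seed=seed)
            cohort = simulate_response_cohort(cfg, n_pd=8, n_cr=21, response_effect=0.4)
            gb = gene_beta_matrix(cohort)
            pd_ids = cohort.samples.index[cohort.samples["response"] == "PD"]
            cr_ids = cohort.samples.index[cohort.samples["response"] == "CR"]
            top = criterion_response_topk(gb[pd_ids], gb[cr_ids], 20)
            hits += "G0500" in top
        assert hits / n_sims >= 0.95


class TestNormalLowCriterion:
    def _panel(self, tissue_means):
        genes = sorted(tissue_means[0])
        rows = []
        ids = []
        tissue_col = []
        beta_cols = {}
        for ti, means in enumerate(tissue_means):
            sid = f"S{ti}"
            ids.append(sid)
            tissue_col.append(f"tissue{ti}")
            beta_cols[sid] = [means[g] for g in genes]
        probes = pd.DataFrame({"gene": genes, "region": "promoter"},
                              index=pd.Index([f"{g}_p1" for g in genes], name="probe_id"))
        samples = pd.DataFrame({"role": "normal_panel", "pair_id": "",
                                "response": "none", "tissue": tissue_col},
                               index=pd.Index(ids, name="sample_id"))
        return ProbeBetaMatrix(pd.DataFrame(beta_cols, index=probes.index), probes, samples)

    def test_all_tissues_low_included(self):
        p = self._panel([{"GA": 0.05}, {"GA": 0.05}])
        assert criterion_normal_low(p, 0.1) == {"GA"}

    def test_one_elevated_tissue_excludes(self):
        p = self._panel([{"GA": 0.05}, {"GA": 0.2}])
        assert criterion_normal_low(p, 0.1) == set()

    def test_background_panel_keeps_nearly_all_genes(self):
        cfg = CohortConfig(n_pairs=2, n_genes=500, background_beta=0.05,
                           noise_sd=0.05, seed=13)
        panel = simulate_normal_panel(cfg)
        kept = criterion_normal_low(panel, 0.1)
        assert len(kept) / cfg.n_genes >= 0.99


class TestExpressionCriterion:
    def test_half_ratio_inclusive(self):
        t = pd.DataFrame({"T1": [50.0]}, index=["GA"])
        n = pd.DataFrame({"N1": [100.0]}, index=["GA"])
        assert criterion_expression_halved(t, n, 0.5) == {"GA"}

    def test_just_above_half_excluded(self):
        t = pd.DataFrame({"T1": [51.0]}, index=["GA"])
        n = pd.DataFrame({"N1": [100.0]}, index=["GA"])
        assert criterion_expression_halved(t, n, 0.5) == set()

    def test_zero_normal_mean_excluded(self):
        t = pd.DataFrame({"T1": [50.0]}, index=["GA"])
        n = pd.DataFrame({"N1": [0.0]}, index=["GA"])
        assert criterion_expression_halved(t, n, 0.5) == set()


def brute_force_funnel(config, inputs):
    """Direct per-gene filtering, no shared code with run_funnel.

    Loops over genes one at a time and applies each rule longhand.
    """
    disc = inputs.discovery
    repl = inputs.replication
    resp = inputs.response
    panel = inputs.normal_panel

    def probe_mean(matrix, gene, sample_ids):
        probe_ids = matrix.probes.index[matrix.probes["gene"] == gene]
        vals = matrix.beta.loc[probe_ids, sample_ids].to_numpy(dtype=float)
        return float(np.nanmean(vals, axis=0).mean())

    genes = sorted(set(disc.probes["gene"]))
    survivors = []
    ranked = []
    pd_ids = resp.samples.index[resp.samples["response"] == "PD"]
    cr_ids = resp.samples.index[resp.samples["response"] == "CR"]
    for g in genes:
        diff = probe_mean(resp, g, pd_ids) - probe_mean(resp, g, cr_ids)
        ranked.append((g, diff))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    topk = {g for g, _ in ranked[: config.top_k_response]}
    rank_order = [g for g, _ in ranked]

    for g in genes:
        d1 = (probe_mean(disc, g, disc.sample_ids("tumor"))
              - probe_mean(disc, g, disc.sample_ids("adjacent_normal")))
        if not d1 > config.delta_beta_cutoff:
            continue
        d2 = (probe_mean(repl, g, repl.sample_ids("tumor"))
              - probe_mean(repl, g, repl.sample_ids("adjacent_normal")))
        if not d2 > config.delta_beta_cutoff:
            continue
        if g not in topk:
            continue
        tissues = panel.samples["tissue"].unique()
        low = all(
            probe_mean(panel, g, panel.samples.index[panel.samples["tissue"] == t])
            < config.normal_panel_max_beta
            for t in tissues
        )
        if not low:
            continue
        ratio = (inputs.expression_tumor.loc[g].mean()
                 / inputs.expression_normal.loc[g].mean())
        if not ratio <= config.expression_ratio_cutoff:
            continue
        survivors.append(g)
    survivors.sort(key=rank_order.index)
    return survivors


def _small_inputs(seed, n_genes=40):
    cfg = CohortConfig(n_pairs=5, n_genes=n_genes, noise_sd=0.05,
                       planted_genes=tuple(f"G{i:04d}" for i in (1, 2, 3)),
                       seed=seed)
    disc = simulate_beta_cohort(cfg)
    repl = simulate_beta_cohort(CohortConfig(
        n_pairs=5, n_genes=n_genes, noise_sd=0.05,
        planted_genes=cfg.planted_genes, seed=seed + 500))
    resp = simulate_response_cohort(cfg, n_pd=4, n_cr=6)
    panel = simulate_normal_panel(cfg, n_tissues=4, samples_per_tissue=6)
    expr = simulate_expression(cfg, disc)
    return cfg, FunnelInputs(
        disc, repl, resp, panel,
        expr[disc.sample_ids("tumor")], expr[disc.sample_ids("adjacent_normal")],
    )


class TestRunFunnel:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cfg, inputs = _small_inputs(seed)
        config = FunnelConfig(top_k_response=10)
        report = run_funnel(config, inputs)
        assert report.final_genes == brute_force_funnel(config, inputs)

    def test_final_subset_of_every_criterion(self):
        _, inputs = _small_inputs(3)
        report = run_funnel(FunnelConfig(top_k_response=10), inputs)
        final = set(report.final_genes)
        for name, genes in report.criterion_sets.items():
            assert final <= genes, name

    def test_relaxing_cutoff_never_shrinks_criterion_set(self):
        _, inputs = _small_inputs(4)
        strict = run_funnel(FunnelConfig(delta_beta_cutoff=0.45, top_k_response=10), inputs)
        relaxed = run_funnel(FunnelConfig(delta_beta_cutoff=0.30, top_k_response=10), inputs)
        assert (strict.criterion_sets["discovery_hypermethylation"]
                <= relaxed.criterion_sets["discovery_hypermethylation"])

    def test_sample_permutation_invariance(self):
        cfg, inputs = _small_inputs(5)
        report1 = run_funnel(FunnelConfig(top_k_response=10), inputs)
        disc = inputs.discovery
        perm = disc.beta.columns[::-1]
        shuffled = FunnelInputs(
            disc.subset_samples(perm), inputs.replication, inputs.response,
            inputs.normal_panel, inputs.expression_tumor, inputs.expression_normal,
        )
        report2 = run_funnel(FunnelConfig(top_k_response=10), shuffled)
        assert report1.final_genes == report2.final_genes

    def test_empty_intersection_still_reports(self):
        cfg, inputs = _small_inputs(6)
        # impossible expression cutoff forces an empty final set
        report = run_funnel(FunnelConfig(top_k_response=10,
                                         expression_ratio_cutoff=0.0), inputs)
        assert report.final_genes == []
        assert report.counts["final"] == 0
        assert report.complete

    def test_partial_report_on_failing_criterion(self):
        cfg, inputs = _small_inputs(7)
        empty = inputs.expression_tumor.iloc[:, :0]
        broken = FunnelInputs(inputs.discovery, inputs.replication, inputs.response,
                              inputs.normal_panel, empty, inputs.expression_normal)
        report = run_funnel(FunnelConfig(top_k_response=10), broken)
        assert "expression_halved" in report.errors
        assert not report.complete
        # remaining criteria still intersect
        assert set(report.final_genes) <= report.criterion_sets["discovery_hypermethylation"]
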