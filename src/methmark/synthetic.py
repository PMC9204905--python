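"""Synthetic cohort generator.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: paired tumor/normal beta
matrices with planted hypermethylated genes, a multi-tissue normal panel,
expression coupled negatively to methylation, Cq values implied by true
relative levels under an efficiency model, plasma trajectories with
treatment clearance and optional progression regrowth, and survival times
with a group-dependent hazard.  All generators are deterministic under a
fixed seed.

Methylation noise is drawn from a Beta distribution with mean equal to the
true methylation fraction and standard deviation ``noise_sd``: values stay
inside [0, 1] with no atom at the bounds, group means converge to the
planted means exactly, and low-background genes get the J-shaped
near-zero distribution typical of unmethylated probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arrays import ProbeBetaMatrix
from .plasma import PlasmaSeries
from .qpcr import MAX_CYCLES_DEFAULT, QpcrMeasurement

__all__ = [
    "CohortConfig",
    "PlasmaSimConfig",
    "simulate_beta_cohort",
    "simulate_response_cohort",
    "simulate_normal_panel",
    "simulate_expression",
    "simulate_qpcr",
    "simulate_plasma_series",
    "simulate_survival",
    "visit_months",
]

#: Tissue types of the multi-tissue normal panel.
PANEL_TISSUES = (
    "breast", "colon", "rectum", "lung", "uterus",
    "stomach", "esophagus", "pancreas", "liver", "prostate",
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the tissue cohorts.

    Defaults plant 20 fully-silenced hypermethylated genes (tumor beta
    lifted by 0.5 over a 0.05 background, expression reduced 4-fold) among
    1000 genes in 20 tumor/normal pairs, with beta noise sd 0.05.
    """

    n_pairs: int = 20
    n_genes: int = 1000
    probes_per_gene: int = 2
    planted_genes: tuple[str, ...] | None = None
    delta_beta_effect: float = 0.5
    background_beta: float = 0.05
    noise_sd: float = 0.05
    responder_fraction: float = 0.7
    expression_coupling: float = 4.0
    expression_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("n_genes and probes_per_gene must be positive")
        for name in ("delta_beta_effect", "background_beta", "responder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.expression_coupling < 1:
            raise ValueError("expression_coupling must be >= 1")
        if self.planted_genes is not None:
            universe = set(self.gene_ids())
            extra = set(self.planted_genes) - universe
            if extra:
                raise ValueError(f"planted genes outside the gene universe: {sorted(extra)}")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def planted(self) -> list[str]:
        if self.planted_genes is not None:
            return list(self.planted_genes)
        return self.gene_ids()[: min(20, self.n_genes)]


@dataclass(frozen=True)
class PlasmaSimConfig:
    """Study-condition parameters for plasma surveillance trajectories.

    Levels are methylated-target/ACTB ratios.  Post-treatment clearance is
    geometric with ``clearance_halflife`` measured in draws; progressors
    regrow geometrically from the detection floor after a random onset
    draw.  Assay noise is multiplicative lognormal with the stated CV, and
    values below ``detection_floor`` are reported as 0 (diminished signal).
    """

    n_patients: int = 200
    baseline_level: float = 0.016
    clearance_halflife: float = 0.5
    progression_fraction: float = 0.5
    regrowth_rate: float = 2.0
    detection_floor: float = 0.002
    assay_cv: float = 0.3
    n_timepoints: int = 9
    cea_baseline: float = 1.5
    ca153_baseline: float = 12.0
    marker_cv: float = 0.3
    cea_late_abnormal_prob: float = 0.4
    ca153_late_abnormal_prob: float = 0.2
    hormone_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_timepoints < 4:
            raise ValueError("need at least 1 patient and 4 timepoints")
        if not 0.0 <= self.progression_fraction <= 1.0:
            raise ValueError("progression_fraction must lie in [0, 1]")
        if self.regrowth_rate <= 1.0:
            raise ValueError("regrowth_rate must exceed 1")
        if min(self.baseline_level, self.detection_floor, self.assay_cv) < 0:
            raise ValueError("levels and CV must be nonnegative")


def visit_months(n_timepoints: int) -> np.ndarray:
    """Surveillance schedule: every 3 months for 2 years, then every 6 months."""
    months, m = [], 0.0
    for _ in range(n_timepoints):
        months.append(m)
        m += 3.0 if m < 24.0 else 6.0
    return np.asarray(months)


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta-distributed draws with the given means and sd; exact when sd == 0.

    The sd is capped just under the Beta-family maximum sqrt(m(1-m)) where
    the requested dispersion is infeasible for a mean near the bounds.
    """
    if sd == 0:
        return mean.copy()
    m = np.clip(mean, 1e-6, 1.0 - 1e-6)
    s = np.minimum(sd, 0.95 * np.sqrt(m * (1.0 - m)))
    nu = m * (1.0 - m) / s**2 - 1.0
    return rng.beta(m * nu, (1.0 - m) * nu)


def _probe_annotation(config: CohortConfig) -> pd.DataFrame:
    genes = config.gene_ids()
    regions = ("promoter", "exon1")
    rows = [
        (f"{g}_p{j + 1}", g, regions[j % 2])
        for g in genes
        for j in range(config.probes_per_gene)
    ]
    ann = pd.DataFrame(rows, columns=["probe_id", "gene", "region"]).set_index("probe_id")
    return ann


def _planted_mean(config: CohortConfig) -> float:
    mean = config.background_beta + config.delta_beta_effect
    if mean > 1.0:
        warnings.warn(
            "planted effect pushes mean beta beyond 1; clipping to 1", stacklevel=3
        )
        mean = 1.0
    return mean


def simulate_beta_cohort(config: CohortConfig) -> ProbeBetaMatrix:
    """Paired tumor / adjacent-normal beta cohort with planted hypermethylation.

    Tumors at planted genes have mean beta ``background + delta_beta_effect``
    (clipped to 1 with a warning); normals and non-planted genes sit at the
    background.  Tumors carry CR/PD response labels in the configured
    responder proportion.
    """
    rng = np.random.default_rng([config.seed, 1])
    ann = _probe_annotation(config)
    planted = set(config.planted())
    planted_probe = ann["gene"].isin(planted).to_numpy()

    n = config.n_pairs
    tumor_ids = [f"T{i:03d}" for i in range(1, n + 1)]
    normal_ids = [f"N{i:03d}" for i in range(1, n + 1)]
    sample_ids = tumor_ids + normal_ids

    mean = np.full((len(ann), 2 * n), config.background_beta)
    mean[np.ix_(planted_probe, np.arange(n))] = _planted_mean(config)
    beta = _beta_noise(rng, mean, config.noise_sd)

    n_cr = int(round(config.responder_fraction * n))
    responses = np.array(["CR"] * n_cr + ["PD"] * (n - n_cr))
    rng.shuffle(responses)
    samples = pd.DataFrame(
        {
            "role": ["tumor"] * n + ["adjacent_normal"] * n,
            "pair_id": [f"P{i:03d}" for i in range(1, n + 1)] * 2,
            "response": list(responses) + ["none"] * n,
            "tissue": "breast",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ProbeBetaMatrix(
        pd.DataFrame(beta, index=ann.index, columns=sample_ids), ann, samples
    )


def simulate_response_cohort(
    config: CohortConfig,
    n_pd: int = 8,
    n_cr: int = 21,
    response_effect: float = 0.4,
) -> ProbeBetaMatrix:
    """Tumor-only cohort contrasting poor (PD) vs complete (CR) responders.

    Planted genes carry mean beta elevated by ``response_effect`` in PD
    tumors relative to the CR background; all other genes are exchangeable
    between the groups.
    """
    if n_pd < 1 or n_cr < 1:
        raise ValueError("both response groups must be nonempty")
    rng = np.random.default_rng([config.seed, 2])
    ann = _probe_annotation(config)
    planted_probe = ann["gene"].isin(set(config.planted())).to_numpy()

    ids = [f"PD{i:03d}" for i in range(1, n_pd + 1)] + [
        f"CR{i:03d}" for i in range(1, n_cr + 1)
    ]
    mean = np.full((len(ann), n_pd + n_cr), config.background_beta)
    pd_mean = min(config.background_beta + response_effect, 1.0)
    mean[np.ix_(planted_probe, np.arange(n_pd))] = pd_mean
    beta = _beta_noise(rng, mean, config.noise_sd)

    samples = pd.DataFrame(
        {
            "role": "tumor",
            "pair_id": "",
            "response": ["PD"] * n_pd + ["CR"] * n_cr,
            "tissue": "breast",
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return ProbeBetaMatrix(pd.DataFrame(beta, index=ann.index, columns=ids), ann, samples)


def simulate_normal_panel(
    config: CohortConfig, n_tissues: int = 10, samples_per_tissue: int = 32
) -> ProbeBetaMatrix:
    """Multi-tissue normal panel: every gene (planted or not) at background beta.

    Defaults emulate a ~320-sample panel spanning ten normal tissue types
    (breast, colon, rectum, lung, uterus, stomach, esophagus, pancreas,
    liver, prostate).
    """
    if n_tissues < 1 or samples_per_tissue < 1:
        raise ValueError("need at least one tissue and one sample per tissue")
    rng = np.random.default_rng([config.seed, 3])
    ann = _probe_annotation(config)
    tissues = [PANEL_TISSUES[i % len(PANEL_TISSUES)] for i in range(n_tissues)]
    ids, tissue_col = [], []
    for i, t in enumerate(tissues):
        for j in range(samples_per_tissue):
            ids.append(f"NP_{t}{i:02d}_{j + 1}")
            tissue_col.append(t)
    mean = np.full((len(ann), len(ids)), config.background_beta)
    beta = _beta_noise(rng, mean, config.noise_sd)
    samples = pd.DataFrame(
        {"role": "normal_panel", "pair_id": "", "response": "none", "tissue": tissue_col},
        index=pd.Index(ids, name="sample_id"),
    )
    return ProbeBetaMatrix(pd.DataFrame(beta, index=ann.index, columns=ids), ann, samples)


def simulate_expression(config: CohortConfig, methylation: ProbeBetaMatrix) -> pd.DataFrame:
    """Gene-by-sample expression coupled negatively to planted methylation.

    Baseline expression is 100 arbitrary units; tumor samples at planted
    hypermethylated genes are reduced ``expression_coupling``-fold.  Noise
    is multiplicative lognormal with CV ``expression_cv`` (mean-one, so the
    planted tumor/normal ratio stays 1/coupling in expectation).
    """
    rng = np.random.default_rng([config.seed, 4])
    genes = config.gene_ids()
    planted = np.isin(genes, config.planted())
    sample_ids = methylation.samples.index
    is_tumor = (methylation.samples["role"] == "tumor").to_numpy()

    expr = np.full((len(genes), len(sample_ids)), 100.0)
    expr[np.ix_(planted, is_tumor)] /= config.expression_coupling
    if config.expression_cv > 0:
        sigma = np.sqrt(np.log1p(config.expression_cv**2))
        expr *= rng.lognormal(-0.5 * sigma**2, sigma, size=expr.shape)
    return pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)


def simulate_qpcr(
    true_ratio: float,
    cq_reference: float = 28.0,
    efficiency: float = 2.0,
    replicates: int = 3,
    cq_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "S1",
    target: str = "TARGET_METH",
    reference: str = "ACTB",
    max_cycles: float = MAX_CYCLES_DEFAULT,
) -> QpcrMeasurement:
    """Cq replicates implied by a true target/reference ratio.

    Inverse of the comparative-Cq model: the noiseless target Cq is
    ``cq_reference - log_E(true_ratio)``.  A true ratio of 0, or a ratio so
    small the implied Cq exceeds the cycle budget, yields the
    no-amplification sentinel (``max_cycles``).  Replicate noise is
    N(0, cq_sd) on both assays.
    """
    if true_ratio < 0:
        raise ValueError("true_ratio must be nonnegative")
    if efficiency <= 1.0:
        raise ValueError("efficiency must exceed 1")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    ref = cq_reference + rng.normal(0.0, cq_sd, size=replicates) if cq_sd > 0 else np.full(
        replicates, cq_reference
    )
    if true_ratio == 0:
        tgt = np.full(replicates, max_cycles)
    else:
        base = cq_reference - np.log(true_ratio) / np.log(efficiency)
        tgt = base + rng.normal(0.0, cq_sd, size=replicates) if cq_sd > 0 else np.full(
            replicates, base
        )
        tgt = np.where(tgt >= max_cycles, max_cycles, np.maximum(tgt, 1e-3))
    return QpcrMeasurement(sample_id, target, reference, tgt, ref, max_cycles=max_cycles)


def simulate_plasma_series(config: PlasmaSimConfig) -> list[PlasmaSeries]:
    """Plasma surveillance trajectories with true progression labels.

    Non-progressors decay geometrically from the baseline level to below
    the detection floor (reported as 0).  Progressors decay likewise, then
    regrow from the floor by ``regrowth_rate`` per draw after a random
    onset in draws 2..n-2.  Serum CEA / CA15-3 stay near their normal
    baselines except for a configurable late abnormality in progressors at
    the final draws.
    """
    rng = np.random.default_rng([config.seed, 5])
    months = visit_months(config.n_timepoints)
    t = np.arange(config.n_timepoints, dtype=float)
    n_prog = int(round(config.progression_fraction * config.n_patients))
    progressor = np.zeros(config.n_patients, dtype=bool)
    progressor[:n_prog] = True
    rng.shuffle(progressor)

    sigma = np.sqrt(np.log1p(config.assay_cv**2)) if config.assay_cv > 0 else 0.0
    msig = np.sqrt(np.log1p(config.marker_cv**2)) if config.marker_cv > 0 else 0.0

    def _noise(size, s):
        if s == 0:
            return np.ones(size)
        return rng.lognormal(-0.5 * s**2, s, size=size)

    cohort: list[PlasmaSeries] = []
    for i in range(config.n_patients):
        decay = config.baseline_level * 0.5 ** (t / config.clearance_halflife)
        level = decay.copy()
        if progressor[i]:
            onset = int(rng.integers(2, config.n_timepoints - 1))
            regrow = np.where(
                t >= onset,
                config.detection_floor * config.regrowth_rate ** (t - onset),
                0.0,
            )
            level = np.maximum(level, regrow)
        level = level * _noise(level.shape, sigma)
        level[level < config.detection_floor] = 0.0

        cea = config.cea_baseline * _noise(level.shape, msig)
        ca153 = config.ca153_baseline * _noise(level.shape, msig)
        if progressor[i]:
            if rng.random() < config.cea_late_abnormal_prob:
                cea[-2:] = 1.6 * 5.0 * _noise(2, msig)
            if rng.random() < config.ca153_late_abnormal_prob:
                ca153[-2:] = 1.6 * 25.0 * _noise(2, msig)

        cohort.append(
            PlasmaSeries(
                patient_id=f"PT{i + 1:03d}",
                months=months,
                levels=level,
                cea=cea,
                ca153=ca153,
                outcome="progression" if progressor[i] else "non_progression",
                therapy="hormone_therapy" if rng.random() < config.hormone_fraction else "other",
            )
        )
    return cohort


def simulate_survival(
    n: int = 500,
    hazard_ratio: float = 6.0,
    group_fraction: float = 0.4,
    censor_time: float = 120.0,
    median_months: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times with a multiplicative group hazard.

    The reference group has median survival ``median_months``; the exposed
    group's hazard is multiplied by ``hazard_ratio``.  Administrative
    censoring at ``censor_time`` months (``censor_time=0`` censors
    everything at 0).  Returns columns time_months, event, group.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if censor_time < 0:
        raise ValueError("censor_time must be nonnegative")
    rng = np.random.default_rng([seed, 6])
    group = (rng.random(n) < group_fraction).astype(int)
    base_hazard = np.log(2.0) / median_months
    times = rng.exponential(1.0 / (base_hazard * hazard_ratio**group))
    event = (times <= censor_time).astype(int)
    times = np.minimum(times, censor_time)
    return pd.DataFrame({"time_months": times, "event": event, "group": group})
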