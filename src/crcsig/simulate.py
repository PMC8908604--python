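"""Synthetic colorectal-cancer cohort generator.

Generates download-free cohorts (expression + clinical + ground truth) with
the statistical structure the downstream analyses assume, so every pipeline
stage can be exercised and parameter recovery quantified:

* CMS1-4 class structure (plus an unclassifiable noise fraction) at
  configurable proportions, with class-specific marker-gene mean shifts;
* four correlated latent signaling axes — MEK-pathway activation (MEK18),
  MEK-inhibitor bypass resistance (MEKIBP), SRC activation (SRC) and EMT —
  drawn multivariate-normal with a configurable correlation matrix and
  class-dependent mean shifts; signature genes load on these axes;
* optional probe-level replication with per-probe offsets and noise;
* mutation flags with class-dependent rates (BRAF V600E enriched in CMS1,
  KRAS/NRAS in CMS3/4, MSI in CMS1) and BRAF/KRAS/NRAS mutual exclusivity;
* stage / primary-metastatic labels drawn per class;
* exponential overall survival with class log-hazard-ratios and a per-SD
  SRC-latent log-hazard-ratio, plus independent exponential censoring.

The generator is a linear-Gaussian latent-factor model: the simplest
construction able to plant correlated resistance/SRC/EMT axes, class
shifts and a survival gradient. It is a statistical test-bed, not a
biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cms import CMSTemplate, CMS_CLASSES
from .expression import ExpressionMatrix
from .signatures import GeneSignature, SignatureRegistry
from .stats import ClinicalTable

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "SimulationError",
    "simulate_cohort",
    "simulate_survival_only",
    "recovery_report",
    "expected_score_correlation",
    "default_latent_correlation",
]

LATENT_AXES = ("MEK18", "MEKIBP", "SRC", "EMT")

# Signature sizes mirror the published gene lists that are consumed as
# inputs on real data: 18-gene MEK activation, 13-gene MEKi bypass,
# 61 UP-gene SRC activation, 5-gene Dasa-S, and an EMT set with both
# up (mesenchymal) and down (epithelial) members.
DEFAULT_SIGNATURE_SIZES = {"MEK18": 18, "MEKIBP": 13, "SRC": 61, "DASAS": 5, "EMT": (20, 5)}

# Axis each signature's genes load on; Dasa-S tracks SRC dependency.
SIGNATURE_AXIS = {"MEK18": "MEK18", "MEKIBP": "MEKIBP", "SRC": "SRC", "DASAS": "SRC", "EMT": "EMT"}


class SimulationError(ValueError):
    pass


def default_latent_correlation() -> pd.DataFrame:
    """Correlations among the four latent axes.

    Strong MEKIBP-SRC (0.9) and SRC-EMT (0.85) coupling versus
    near-independence of MEK18 from MEKIBP (0.05); the unspecified pairs are
    filled with single-factor products so the matrix is positive
    semi-definite by construction.
    """
    r = pd.DataFrame(np.eye(4), index=list(LATENT_AXES), columns=list(LATENT_AXES))
    pairs = {
        ("MEKIBP", "SRC"): 0.90,
        ("SRC", "EMT"): 0.85,
        ("MEK18", "MEKIBP"): 0.05,
        ("MEKIBP", "EMT"): 0.90 * 0.85,
        ("MEK18", "SRC"): 0.05 * 0.90,
        ("MEK18", "EMT"): 0.05 * 0.90 * 0.85,
    }
    for (a, b), v in pairs.items():
        r.loc[a, b] = r.loc[b, a] = v
    return r


# Class-conditional mean shifts of the latent axes, in SD units. CMS4 is
# mesenchymal/SRC-high, CMS1 has the highest MEK-pathway output and
# intermediate bypass/SRC, CMS2/CMS3 are epithelial (low SRC/EMT).
DEFAULT_CLASS_LATENT_SHIFTS = {
    "CMS1": {"MEK18": 1.0, "MEKIBP": 0.6, "SRC": 0.5, "EMT": 0.2},
    "CMS2": {"MEK18": -0.2, "MEKIBP": -0.6, "SRC": -0.6, "EMT": -0.6},
    "CMS3": {"MEK18": 0.2, "MEKIBP": -0.4, "SRC": -0.4, "EMT": -0.4},
    "CMS4": {"MEK18": 0.0, "MEKIBP": 1.0, "SRC": 1.1, "EMT": 1.2},
    "NOISE": {},
}

DEFAULT_MUTATION_MODEL = {
    # per-class marginal probabilities; BRAF excludes KRAS/NRAS per sample
    "braf_v600e": {"CMS1": 0.45, "CMS2": 0.04, "CMS3": 0.08, "CMS4": 0.07, "NOISE": 0.08},
    "kras": {"CMS1": 0.20, "CMS2": 0.30, "CMS3": 0.55, "CMS4": 0.45, "NOISE": 0.35},
    "nras": {"CMS1": 0.02, "CMS2": 0.04, "CMS3": 0.05, "CMS4": 0.05, "NOISE": 0.04},
    "msi": {"CMS1": 0.60, "CMS2": 0.04, "CMS3": 0.12, "CMS4": 0.08, "NOISE": 0.10},
}

# Fraction of primaries and stage distribution per class, patterned on the
# composition of a large mixed primary/metastatic CRC cohort.
DEFAULT_PRIMARY_FRACTION = {
    "CMS1": 0.79, "CMS2": 0.59, "CMS3": 0.89, "CMS4": 0.60, "NOISE": 0.55,
}
DEFAULT_STAGE_PROBS = {"I": 0.18, "II": 0.32, "III": 0.36, "IV": 0.10, "NA": 0.04}


@dataclass
class SyntheticCohortConfig:
    """All knobs of the generator; fully determines a cohort given a seed."""

    n_samples: int = 400
    # CMS1..CMS4 then unclassifiable-noise fraction; patterned on the class
    # mix of a large mixed CRC cohort (13.6/30.0/15.4/30.4/10.6%).
    class_proportions: tuple = (0.136, 0.300, 0.154, 0.304, 0.106)
    n_genes_background: int = 200
    markers_per_class: int = 50
    marker_effect: float = 2.0
    latent_correlation: pd.DataFrame = field(default_factory=default_latent_correlation)
    class_latent_shifts: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_LATENT_SHIFTS.items()}
    )
    signature_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_SIZES))
    probes_per_gene: tuple = (1, 1)  # inclusive range; (1,1) = gene-level
    probe_noise_sd: float = 0.3
    mutation_model: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MUTATION_MODEL.items()}
    )
    primary_fraction: dict = field(default_factory=lambda: dict(DEFAULT_PRIMARY_FRACTION))
    stage_probs: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    baseline_hazard: float = 5e-4  # per day; median OS ~ 3.8 years at HR 1
    class_log_hr: dict = field(
        default_factory=lambda: {"CMS1": 0.35, "CMS2": 0.0, "CMS3": 0.0, "CMS4": 0.45, "NOISE": 0.1}
    )
    src_log_hr: float = 0.30  # per SD of the SRC latent axis
    censoring_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != 5 or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise SimulationError("class_proportions must be 5 non-negative values summing to 1")
        corr = self.latent_correlation.loc[list(LATENT_AXES), list(LATENT_AXES)].to_numpy()
        if not np.allclose(corr, corr.T):
            raise SimulationError("latent correlation matrix must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise SimulationError("latent correlation matrix must be positive semi-definite")
        for gene_probs in self.mutation_model.values():
            for p in gene_probs.values():
                if not 0 <= p <= 1:
                    raise SimulationError("mutation probabilities must lie in [0,1]")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise SimulationError("probes_per_gene must be an inclusive range with lo >= 1")


@dataclass
class SyntheticCohort:
    """Expression, clinical annotations and ground truth for one cohort."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: pd.DataFrame  # true_class, latent axis values, true_hazard
    registry: SignatureRegistry
    template: CMSTemplate
    config: SyntheticCohortConfig


def _build_registry(sizes: dict) -> tuple[SignatureRegistry, dict[str, list[str]]]:
    """Signature registry over synthetic gene names, plus axis gene lists."""
    registry = SignatureRegistry()
    axis_genes: dict[str, list[str]] = {a: [] for a in LATENT_AXES}
    for name, size in sizes.items():
        axis = SIGNATURE_AXIS[name]
        if isinstance(size, tuple):  # (n_up, n_down): down genes anti-load
            n_up, n_down = size
            up = [f"{name}U{i:03d}" for i in range(n_up)]
            down = [f"{name}D{i:03d}" for i in range(n_down)]
            registry.add(GeneSignature(name=name, up_genes=frozenset(up),
                                       down_genes=frozenset(down), source="synthetic"))
            axis_genes[axis].extend(up)
            axis_genes[axis].extend("-" + g for g in down)
        else:
            up = [f"{name}U{i:03d}" for i in range(size)]
            registry.add(GeneSignature(name=name, up_genes=frozenset(up), source="synthetic"))
            axis_genes[axis].extend(up)
    return registry, axis_genes


def simulate_cohort(config: SyntheticCohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Draw a full cohort from the generative model; bit-reproducible per seed."""
    config = replace(config or SyntheticCohortConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(int(config.seed) % (2**31))
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    class_names = list(CMS_CLASSES) + ["NOISE"]

    classes = rng.choice(class_names, size=n, p=np.asarray(config.class_proportions, float))

    # latent axes: MVN(shift_class, R)
    corr = config.latent_correlation.loc[list(LATENT_AXES), list(LATENT_AXES)].to_numpy()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    latents = rng.standard_normal((n, 4)) @ chol.T
    for i, cls in enumerate(classes):
        shifts = config.class_latent_shifts.get(cls, {})
        for j, axis in enumerate(LATENT_AXES):
            latents[i, j] += shifts.get(axis, 0.0)
    latent_df = pd.DataFrame(latents, index=sample_ids, columns=list(LATENT_AXES))

    registry, axis_genes = _build_registry(config.signature_sizes)

    # gene-level values
    gene_rows: dict[str, np.ndarray] = {}
    for j, axis in enumerate(LATENT_AXES):
        for g in axis_genes[axis]:
            sign, gene = (-1.0, g[1:]) if g.startswith("-") else (1.0, g)
            gene_rows[gene] = sign * latents[:, j] + rng.standard_normal(n)

    marker_names: dict[str, list[str]] = {}
    for k, cls in enumerate(CMS_CLASSES):
        names = [f"MK{cls}{i:03d}" for i in range(config.markers_per_class)]
        marker_names[cls] = names
        shift = (classes == cls).astype(float) * config.marker_effect
        for gname in names:
            gene_rows[gname] = shift + rng.standard_normal(n)

    for i in range(config.n_genes_background):
        gene_rows[f"BG{i:04d}"] = rng.standard_normal(n)

    gene_df = pd.DataFrame(gene_rows, index=sample_ids).T  # genes x samples

    lo, hi = config.probes_per_gene
    if hi > 1:
        probe_rows = {}
        probe_map = {}
        for gene in gene_df.index:
            k = int(rng.integers(lo, hi + 1))
            for p in range(k):
                pid = f"{gene}_p{p+1}"
                offset = rng.normal(0.0, 0.5)
                probe_rows[pid] = (
                    gene_df.loc[gene].to_numpy()
                    + offset
                    + rng.normal(0.0, config.probe_noise_sd, size=n)
                )
                probe_map[pid] = gene
        expr = ExpressionMatrix(
            values=pd.DataFrame(probe_rows, index=sample_ids).T,
            feature_kind="probe",
            probe_to_gene=probe_map,
        )
    else:
        expr = ExpressionMatrix(values=gene_df, feature_kind="gene")

    template = CMSTemplate(class_markers={c: set(marker_names[c]) for c in CMS_CLASSES})

    # clinical layer
    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clin["age"] = np.round(rng.normal(64.0, 11.0, size=n).clip(18, 95), 1)
    clin["sex"] = rng.choice(["F", "M"], size=n, p=[0.474, 0.526])
    p_primary = np.array([config.primary_fraction.get(c, 0.6) for c in classes])
    primary = rng.random(n) < p_primary
    clin["site_type"] = np.where(primary, "primary", "metastatic")
    sub = np.empty(n, dtype=object)
    sub[primary] = rng.choice(["recurrent", "other"], size=int(primary.sum()), p=[0.2, 0.8])
    sub[~primary] = rng.choice(["regional", "distant"], size=int((~primary).sum()), p=[0.2, 0.8])
    clin["site_subtype"] = sub
    stages = np.array(list(config.stage_probs), dtype=object)
    stage_p = np.array(list(config.stage_probs.values()), dtype=float)
    stage_col = np.full(n, None, dtype=object)
    stage_col[primary] = rng.choice(stages, size=int(primary.sum()), p=stage_p / stage_p.sum())
    clin["stage"] = stage_col

    # mutations: BRAF first; BRAF excludes KRAS/NRAS
    def per_class(probs):
        return np.array([probs.get(c, 0.0) for c in classes])

    braf = rng.random(n) < per_class(config.mutation_model["braf_v600e"])
    kras = (~braf) & (rng.random(n) < per_class(config.mutation_model["kras"]))
    nras = (~braf) & (~kras) & (rng.random(n) < per_class(config.mutation_model["nras"]))
    clin["braf_v600e"] = braf
    clin["kras"] = kras
    clin["nras"] = nras
    clin["msi"] = np.where(
        rng.random(n) < per_class(config.mutation_model["msi"]), "MSI", "MSS"
    )

    # survival: exponential with hazard = base * exp(class log-HR + src log-HR * SRC latent)
    log_hr = np.array([config.class_log_hr.get(c, 0.0) for c in classes])
    hazard = config.baseline_hazard * np.exp(log_hr + config.src_log_hr * latents[:, 2])
    event_time = rng.exponential(1.0 / hazard)
    c = config.censoring_rate
    if c > 0:
        mu = config.baseline_hazard * c / (1.0 - c)
        censor_time = rng.exponential(1.0 / mu, size=n)
    else:
        censor_time = np.full(n, np.inf)
    clin["os_time"] = np.minimum(event_time, censor_time)
    clin["os_event"] = event_time <= censor_time

    truth = pd.DataFrame(
        {"true_class": np.where(classes == "NOISE", "NA", classes), "true_hazard": hazard},
        index=pd.Index(sample_ids, name="sample_id"),
    ).join(latent_df)

    return SyntheticCohort(
        expression=expr,
        clinical=ClinicalTable(df=clin),
        truth=truth,
        registry=registry,
        template=template,
        config=config,
    )


def simulate_survival_only(
    n: int,
    quartile_log_hr: float,
    baseline_hazard: float = 5e-4,
    censoring_rate: float = 0.25,
    seed: int = 0,
):
    """Fast survival-only draw: standard-normal scores with a per-quartile
    hazard gradient ``exp(quartile_log_hr * quartile_index)``.

    Used for power studies where the expression layer is irrelevant.
    Returns (scores Series, clinical DataFrame).
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    scores = pd.Series(rng.standard_normal(n), index=[f"S{i:04d}" for i in range(n)], name="score")
    q_idx = np.searchsorted(np.quantile(scores, [0.25, 0.5, 0.75]), scores, side="left")
    hazard = baseline_hazard * np.exp(quartile_log_hr * q_idx)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        mu = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        censor_time = rng.exponential(1.0 / mu, size=n)
    else:
        censor_time = np.full(n, np.inf)
    clin = pd.DataFrame(
        {"os_time": np.minimum(event_time, censor_time), "os_event": event_time <= censor_time},
        index=scores.index,
    )
    return scores, clin


def expected_score_correlation(
    rho: float, k_a: int, k_b: int, noise_var: float = 1.0, latent_var: float = 1.0
) -> float:
    """Attenuated correlation between two signature scores.

    A score averaging k genes, each gene = latent + N(0, noise_var), has
    variance latent_var + noise_var / k; the covariance between two scores
    on different axes is rho * latent_var. Hence
    corr = rho * latent_var / sqrt((latent_var + noise_var/k_a)
                                   * (latent_var + noise_var/k_b)).
    """
    va = latent_var + noise_var / k_a
    vb = latent_var + noise_var / k_b
    return float(rho * latent_var / np.sqrt(va * vb))


def recovery_report(
    cohort: SyntheticCohort,
    scores: pd.DataFrame | None = None,
    cms_labels: pd.Series | None = None,
    logrank_result: tuple | None = None,
) -> dict:
    """Compare pipeline outputs against the cohort's planted ground truth.

    Reports NTP label accuracy (over samples whose true class is CMS1-4),
    estimated signature-score Spearman correlations next to the planted
    latent correlations, log-rank detection of the planted hazard, and
    mutation-class enrichment odds ratios. Sample sets must match.
    """
    out: dict = {}
    truth = cohort.truth
    if cms_labels is not None:
        if not truth.index.equals(cms_labels.index):
            raise SimulationError("cms_labels index does not match cohort samples")
        real = truth["true_class"] != "NA"
        out["ntp_accuracy"] = float(
            (cms_labels[real] == truth.loc[real, "true_class"]).mean()
        )
        out["ntp_na_rate_on_noise"] = (
            float((cms_labels[~real] == "NA").mean()) if (~real).any() else np.nan
        )
    if scores is not None:
        if not truth.index.equals(scores.index):
            raise SimulationError("score table index does not match cohort samples")
        from .stats import correlation_matrix

        cm = correlation_matrix(scores, method="spearman")
        planted = cohort.config.latent_correlation
        pairs = {}
        for a, b in [("MEKIBP", "SRC"), ("SRC", "EMT"), ("MEK18", "MEKIBP")]:
            if a in scores.columns and b in scores.columns:
                pairs[f"{a}-{b}"] = {
                    "planted_latent": float(planted.loc[a, b]),
                    "recovered": float(cm.rho.loc[a, b]),
                }
        out["correlations"] = pairs
    if logrank_result is not None:
        out["logrank_statistic"], out["logrank_p"] = map(float, logrank_result)
    # mutation-class enrichment: odds of BRAF in CMS1 vs rest, KRAS/NRAS in CMS3/4 vs rest
    clin = cohort.clinical.df
    cls = truth["true_class"]
    def odds_ratio(flag: pd.Series, in_classes: set) -> float:
        a = int((flag & cls.isin(in_classes)).sum())
        b = int((~flag & cls.isin(in_classes)).sum())
        c = int((flag & ~cls.isin(in_classes)).sum())
        d = int((~flag & ~cls.isin(in_classes)).sum())
        if min(b, c) == 0:
            return np.inf
        return (a * d) / (b * c) if a * d else 0.0
    out["braf_cms1_odds_ratio"] = odds_ratio(clin["braf_v600e"], {"CMS1"})
    out["rasmut_cms34_odds_ratio"] = odds_ratio(
        clin["kras"] | clin["nras"], {"CMS3", "CMS4"}
    )
    return out
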