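"""Per-sample signature scores.

A raw component score is the arithmetic mean of all matrix features
(probesets pooled directly, not averaged per gene first) mapping to the
component's gene symbols. Composite modes:

* ``up_only``          -> UP mean
* ``up_minus_down``    -> UP mean - DOWN mean
* ``full_composite``   -> (UP mean + PLUSINF mean) - (DOWN mean + MINUSINF mean)

Cohort scores are standardized by subtracting the score median and dividing
by the score interquartile range (IQR = Q3 - Q1); quartiles throughout use
linearly interpolated sample quantiles (NumPy's default, "type 7"). Cell-line
panels are first normalized per probe by the probe's mean over all samples,
so probes spanning orders of magnitude do not dominate the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .signatures import GeneSignature, SignatureRegistry

__all__ = [
    "ScoreTable",
    "ScoringError",
    "MissingSignatureError",
    "DegenerateScoreError",
    "NormalizationError",
    "raw_component_score",
    "component_means",
    "signature_score",
    "standardize",
    "normalize_cell_line_probes",
    "assign_quartiles",
    "score_pipeline",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


class ScoringError(ValueError):
    pass


class MissingSignatureError(ScoringError):
    """No feature on the platform maps to the signature's genes."""


class DegenerateScoreError(ScoringError):
    """Score column with zero IQR cannot be standardized."""


class NormalizationError(ScoringError):
    """Cell-line probe normalization hit a feature with non-positive mean."""


@dataclass
class ScoreTable:
    """Samples x signatures score matrix with audit metadata.

    ``coverage`` is the fraction of each signature's genes found on the
    platform; ``components`` retains the raw UP/DOWN/+inf/-inf component
    means per signature; ``degenerate`` lists columns whose raw scores had
    zero IQR and were left unstandardized.
    """

    scores: pd.DataFrame
    standardized: bool = False
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    components: dict[str, pd.DataFrame] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = self.coverage[(self.coverage < 0) | (self.coverage > 1)]
        if len(bad):
            raise ScoringError(f"coverage outside [0,1] for {list(bad.index)}")

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.scores.to_csv(fh, sep="\t", index_label="sample_id")


def component_means(
    expr: ExpressionMatrix,
    genes,
    *,
    signature_name: str = "<anonymous>",
    min_coverage: float = 0.5,
    on_low_coverage: str = "warn",
) -> pd.Series:
    """Per-sample arithmetic mean over all features matching the gene set.

    Probe-level features mapping to the same gene are pooled directly into
    the mean, not collapsed per gene first. Raises
    :class:`MissingSignatureError` when nothing matches; coverage below
    ``min_coverage`` warns (or raises when ``on_low_coverage="error"``).
    """
    genes = set(genes)
    feats = expr.features_for_genes(genes)
    if not feats:
        raise MissingSignatureError(
            f"signature {signature_name!r}: no features map to its {len(genes)} genes"
        )
    cov = len(expr.genes_present(genes)) / len(genes)
    if cov < min_coverage:
        msg = (
            f"signature {signature_name!r}: platform coverage {cov:.2f} "
            f"below minimum {min_coverage:.2f}"
        )
        if on_low_coverage == "error":
            raise MissingSignatureError(msg)
        warnings.warn(msg)
    return expr.values.loc[feats].mean(axis=0)


def raw_component_score(
    expr: ExpressionMatrix, genes, sample: str, **kwargs
) -> float:
    """Scalar component score for one sample; see :func:`component_means`."""
    return float(component_means(expr, genes, **kwargs).loc[sample])


def signature_score(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    mode: str | None = None,
    *,
    min_coverage: float = 0.5,
    on_low_coverage: str = "warn",
    return_components: bool = False,
):
    """Per-sample raw score for a signature under the given composite mode.

    ``mode=None`` uses the signature's default (``up_minus_down`` when a
    DOWN set exists, else ``up_only``). In ``full_composite`` mode missing
    optional components contribute 0 with a warning.
    """
    mode = mode or sig.default_mode
    if mode not in ("up_only", "up_minus_down", "full_composite"):
        raise ScoringError(f"unknown scoring mode {mode!r}")

    kw = dict(
        signature_name=sig.name, min_coverage=min_coverage, on_low_coverage=on_low_coverage
    )
    comp = pd.DataFrame(index=expr.values.columns)
    comp["UP"] = component_means(expr, sig.up_genes, **kw)

    if mode == "up_only":
        score = comp["UP"]
    elif mode == "up_minus_down":
        if not sig.down_genes:
            raise ScoringError(
                f"signature {sig.name!r}: up_minus_down mode requires a DOWN component"
            )
        comp["DOWN"] = component_means(expr, sig.down_genes, **kw)
        score = comp["UP"] - comp["DOWN"]
    else:  # full_composite
        zeros = pd.Series(0.0, index=expr.values.columns)
        for label, genes in (
            ("DOWN", sig.down_genes),
            ("PLUSINF", sig.plus_inf_genes),
            ("MINUSINF", sig.minus_inf_genes),
        ):
            if genes:
                comp[label] = component_means(expr, genes, **kw)
            else:
                warnings.warn(
                    f"signature {sig.name!r}: component {label} empty; contributes 0"
                )
                comp[label] = zeros
        score = (comp["UP"] + comp["PLUSINF"]) - (comp["DOWN"] + comp["MINUSINF"])

    score = score.rename(sig.name)
    return (score, comp) if return_components else score


def standardize(scores: pd.Series) -> pd.Series:
    """Center by the median and scale by the IQR (Q3 - Q1, interpolated).

    The transform is strictly monotone, so rank statistics are unchanged.
    Raises :class:`DegenerateScoreError` when the IQR is zero.
    """
    arr = np.asarray(scores, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if iqr <= 0:
        raise DegenerateScoreError(
            f"score column {scores.name!r} has zero IQR; cannot standardize"
        )
    return (scores - med) / iqr


def normalize_cell_line_probes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each feature row by its mean across all samples.

    Used for cell-line panels where probe intensities of different signature
    genes differ by orders of magnitude; every output row has mean 1.
    Features with non-positive means are rejected by name.
    """
    means = expr.values.mean(axis=1)
    bad = means[means <= 0]
    if len(bad):
        raise NormalizationError(
            f"features with non-positive mean cannot be ratio-normalized: "
            f"{list(bad.index[:5])}{'...' if len(bad) > 5 else ''}"
        )
    return ExpressionMatrix(
        values=expr.values.div(means, axis=0),
        feature_kind=expr.feature_kind,
        probe_to_gene=dict(expr.probe_to_gene) if expr.probe_to_gene else None,
    )


def assign_quartiles(scores: pd.Series) -> pd.Series:
    """Quartile labels Q1 (lowest) .. Q4 (highest) by interpolated quantiles.

    Values exactly on a 25/50/75% cut point go to the lower group. A
    degenerate all-equal column collapses to Q1 with a warning.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 4:
        raise ScoringError(f"need >=4 samples to form quartiles, got {arr.size}")
    cuts = np.quantile(arr, [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        warnings.warn("degenerate score distribution: all samples in Q1")
    # boundary-low rule: count of cut points strictly below the value
    idx = np.searchsorted(cuts, arr, side="left")
    labels = np.asarray(QUARTILE_LABELS)[idx]
    return pd.Series(
        pd.Categorical(labels, categories=list(QUARTILE_LABELS), ordered=True),
        index=scores.index,
        name=scores.name,
    )


def score_pipeline(
    expr: ExpressionMatrix,
    registry: SignatureRegistry,
    cell_line_mode: bool = False,
    *,
    min_coverage: float = 0.5,
    on_low_coverage: str = "warn",
    log2_transform: bool = False,
    mode_overrides: dict[str, str] | None = None,
) -> ScoreTable:
    """Score every registry signature and standardize each column.

    Stages: optional log2(x+1) pre-transform; optional cell-line probe
    normalization; per-signature raw composite score (default mode unless
    overridden); median/IQR standardization. Columns with zero IQR are kept
    raw and flagged in ``degenerate``. Deterministic: identical inputs give
    bit-identical output.
    """
    mode_overrides = mode_overrides or {}
    if log2_transform:
        if (expr.values.to_numpy() < 0).any():
            raise ScoringError("log2 transform requires non-negative values")
        expr = ExpressionMatrix(
            values=np.log2(expr.values + 1.0),
            feature_kind=expr.feature_kind,
            probe_to_gene=dict(expr.probe_to_gene) if expr.probe_to_gene else None,
        )
    if cell_line_mode:
        expr = normalize_cell_line_probes(expr)

    cols: dict[str, pd.Series] = {}
    coverage: dict[str, float] = {}
    components: dict[str, pd.DataFrame] = {}
    degenerate: list[str] = []
    for sig in registry:
        raw, comp = signature_score(
            expr,
            sig,
            mode_overrides.get(sig.name),
            min_coverage=min_coverage,
            on_low_coverage=on_low_coverage,
            return_components=True,
        )
        components[sig.name] = comp
        coverage[sig.name] = len(expr.genes_present(sig.all_genes)) / len(sig.all_genes)
        try:
            cols[sig.name] = standardize(raw)
        except DegenerateScoreError:
            warnings.warn(f"signature {sig.name!r}: zero IQR, column left unstandardized")
            degenerate.append(sig.name)
            cols[sig.name] = raw
    return ScoreTable(
        scores=pd.DataFrame(cols, index=expr.values.columns),
        standardized=True,
        coverage=pd.Series(coverage, name="coverage"),
        components=components,
        degenerate=degenerate,
    )
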