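"""Consensus-molecular-subtype (CMS) calls by nearest-template prediction.

Colorectal tumors are assigned to one of four transcriptome-defined classes
(CMS1 MSI/immune, CMS2 canonical, CMS3 metabolic, CMS4 mesenchymal) by
comparing each sample's marker-gene expression vector against per-class
marker templates. For each sample and class k we report a distance
``dCMSk`` in [0, 1] — here ``d = (1 - cosine similarity) / 2`` between the
row-standardized marker vector and the class indicator template — a
permutation p-value for the nearest class (template gene labels shuffled
within the sample, add-one smoothing), a Benjamini-Hochberg FDR across
samples, the class label (argmin distance, or NA when FDR exceeds the
threshold), and propensity scores ``CMSk* = 1 - dCMSk``: the higher the
distance, the lower the propensity to fall in that class.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "CMS_CLASSES",
    "CMSTemplate",
    "CMSResult",
    "CMSError",
    "template_distance",
    "ntp_classify",
    "propensity_scores",
    "read_template_tsv",
]

CMS_CLASSES = ("CMS1", "CMS2", "CMS3", "CMS4")


class CMSError(ValueError):
    pass


@dataclass(frozen=True)
class CMSTemplate:
    """Per-class marker gene sets; each gene belongs to exactly one class."""

    class_markers: dict

    def __post_init__(self) -> None:
        if set(self.class_markers) != set(CMS_CLASSES):
            raise CMSError(f"template must define exactly the classes {CMS_CLASSES}")
        sets = {k: frozenset(map(str.upper, v)) for k, v in self.class_markers.items()}
        for k, genes in sets.items():
            if not genes:
                raise CMSError(f"template class {k} has no marker genes")
        total = sum(len(s) for s in sets.values())
        if len(frozenset().union(*sets.values())) != total:
            raise CMSError("template marker sets must be pairwise disjoint")
        object.__setattr__(self, "class_markers", sets)

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for k in CMS_CLASSES:
            out.extend(sorted(self.class_markers[k]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("gene_symbol\tclass\n")
            for k in CMS_CLASSES:
                for g in sorted(self.class_markers[k]):
                    fh.write(f"{g}\t{k}\n")


def read_template_tsv(path: str | Path) -> CMSTemplate:
    """Read a (gene_symbol, class) TSV into a template."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise CMSError("template file needs columns: gene_symbol, class")
    markers: dict[str, set[str]] = {k: set() for k in CMS_CLASSES}
    for gene, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if cls not in markers:
            raise CMSError(f"unknown class label {cls!r} in template")
        markers[cls].add(str(gene).strip().upper())
    return CMSTemplate(class_markers=markers)


@dataclass
class CMSResult:
    """Per-sample distances, confidence and labels from NTP classification.

    ``table`` columns: dCMS1..dCMS4, p_value, fdr, label (CMS1..CMS4 or
    "NA"), CMS1*..CMS4*.
    """

    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def distances(self) -> pd.DataFrame:
        return self.table[[f"d{k}" for k in CMS_CLASSES]]

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index_label="sample_id")


def _cosine_distance(vec: np.ndarray, tmpl: np.ndarray) -> float:
    denom = np.linalg.norm(vec) * np.linalg.norm(tmpl)
    if denom == 0:
        return 0.5  # undefined direction: treat as orthogonal
    cos = float(vec @ tmpl) / denom
    return float(np.clip((1.0 - cos) / 2.0, 0.0, 1.0))


def template_distance(sample_profile: pd.Series, template: CMSTemplate, cls: str) -> float:
    """Distance in [0, 1] from one sample's marker profile to a class template.

    ``sample_profile`` maps gene symbol to (cohort row-standardized)
    expression; only genes in the template universe are used. Distance is
    ``(1 - cosine)/2`` against the class indicator vector, so a profile
    aligned with the template scores 0, an anti-aligned one 1, an orthogonal
    one 0.5.
    """
    if cls not in CMS_CLASSES:
        raise CMSError(f"unknown class {cls!r}")
    genes = [g for g in template.all_genes if g in sample_profile.index]
    if len(genes) < 2:
        raise CMSError("fewer than 2 template genes present; sample unclassifiable")
    vec = sample_profile.loc[genes].to_numpy(dtype=float)
    tmpl = np.array([1.0 if g in template.class_markers[cls] else 0.0 for g in genes])
    return _cosine_distance(vec, tmpl)


def _sample_substream(seed: int, sample_id: str) -> np.random.Generator:
    # Per-sample stream keyed by id hash: classification is invariant to
    # sample order within the matrix.
    tag = zlib.crc32(str(sample_id).encode("utf-8")) % (2**31)
    return np.random.default_rng([int(seed) % (2**31), tag])


def ntp_classify(
    expr: ExpressionMatrix,
    template: CMSTemplate,
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> CMSResult:
    """Nearest-template prediction over a cohort.

    Marker genes present on the platform are gene-wise centered and scaled
    across the cohort; each sample's distance to each class template is
    computed; the nearest class's p-value is the add-one-smoothed fraction
    of within-sample gene-label permutations achieving a distance at most
    the observed one; labels with Benjamini-Hochberg FDR above
    ``fdr_threshold`` are set to NA. Deterministic given ``seed`` and
    invariant to sample order.
    """
    if not (0 < fdr_threshold < 1):
        raise CMSError("fdr_threshold must be in (0, 1)")
    if n_perm < 1:
        raise CMSError("n_perm must be positive")

    genes = [g for g in template.all_genes if g in expr._gene_to_features]
    if len(genes) < 2:
        raise CMSError("fewer than 2 template genes present on the platform")
    # collapse to gene level (mean over probes) then row-standardize
    rows = {}
    for g in genes:
        feats = expr.features_for_genes([g])
        rows[g] = expr.values.loc[feats].mean(axis=0)
    mat = pd.DataFrame(rows).T  # genes x samples
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    keep = sd > 0
    mat = mat.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    genes = list(mat.index)
    if len(genes) < 2:
        raise CMSError("degenerate template: fewer than 2 variable marker genes")

    templates = np.stack(
        [
            np.array([1.0 if g in template.class_markers[k] else 0.0 for g in genes])
            for k in CMS_CLASSES
        ]
    )  # 4 x G
    tmpl_norms = np.linalg.norm(templates, axis=1)
    if (tmpl_norms == 0).any():
        raise CMSError("degenerate template: a class has no variable marker genes")

    X = mat.to_numpy(dtype=float).T  # samples x G
    sample_ids = [str(c) for c in mat.columns]
    x_norms = np.linalg.norm(X, axis=1)
    x_norms[x_norms == 0] = 1.0
    cos = (X @ templates.T) / x_norms[:, None] / tmpl_norms[None, :]
    dist = np.clip((1.0 - cos) / 2.0, 0.0, 1.0)  # samples x 4
    best_idx = dist.argmin(axis=1)

    pvals = np.empty(len(sample_ids))
    for i, sid in enumerate(sample_ids):
        rng = _sample_substream(seed, sid)
        x = X[i]
        perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)  # n_perm x G
        t = templates[best_idx[i]]
        cos_p = (perms @ t) / (np.linalg.norm(x) or 1.0) / tmpl_norms[best_idx[i]]
        d_p = np.clip((1.0 - cos_p) / 2.0, 0.0, 1.0)
        pvals[i] = (1.0 + np.sum(d_p <= dist[i, best_idx[i]])) / (n_perm + 1.0)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    labels = np.where(
        fdr <= fdr_threshold, np.asarray(CMS_CLASSES)[best_idx], "NA"
    )

    table = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for j, k in enumerate(CMS_CLASSES):
        table[f"d{k}"] = dist[:, j]
    table["p_value"] = pvals
    table["fdr"] = fdr
    table["label"] = labels
    for k in CMS_CLASSES:
        table[f"{k}*"] = 1.0 - table[f"d{k}"]
    result = CMSResult(table=table)
    return result


def propensity_scores(result: CMSResult) -> pd.DataFrame:
    """Propensity of each sample for each class: ``CMSk* = 1 - dCMSk``.

    Exact affine transform of the distances; for every non-NA sample the
    argmax propensity equals the assigned label.
    """
    dist = result.distances
    arr = dist.to_numpy()
    if ((arr < 0) | (arr > 1)).any():
        raise CMSError("distances outside [0,1] violate the dCMS contract")
    prop = 1.0 - dist
    prop.columns = [f"{k}*" for k in CMS_CLASSES]
    return prop
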