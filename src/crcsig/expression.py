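"""Expression-matrix container and tab-delimited I/O.

Matrices are features x samples, either probe-level (with a probe-to-gene
symbol map, as for Affymetrix arrays) or gene-level (as for RSEM
gene-normalized RNA-seq). Values must be finite; missing-value handling is
the caller's responsibility upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import normalize_symbol

__all__ = ["ExpressionMatrix", "ExpressionError", "read_expression_tsv", "read_probe_map"]


class ExpressionError(ValueError):
    """Invalid expression matrix (non-finite values, duplicate ids...)."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    feature_kind
        ``"probe"`` or ``"gene"``. Probe-level matrices require
        ``probe_to_gene``.
    probe_to_gene
        Map from probe id to gene symbol; symbols are normalized on
        construction.
    """

    values: pd.DataFrame
    feature_kind: str = "gene"
    probe_to_gene: dict[str, str] | None = None
    _gene_to_features: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.feature_kind not in ("probe", "gene"):
            raise ExpressionError(f"feature_kind must be 'probe' or 'gene', got {self.feature_kind!r}")
        if self.values.index.has_duplicates:
            raise ExpressionError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ExpressionError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ExpressionError("expression values must be finite (impute or drop upstream)")
        if self.feature_kind == "probe":
            if self.probe_to_gene is None:
                raise ExpressionError("probe-level matrix requires a probe_to_gene map")
            self.probe_to_gene = {
                str(p): normalize_symbol(g) for p, g in self.probe_to_gene.items()
            }
        # Index features by gene symbol once; scoring hits this repeatedly.
        gene_to_features: dict[str, list[str]] = {}
        if self.feature_kind == "gene":
            for fid in self.values.index:
                gene_to_features.setdefault(normalize_symbol(str(fid)), []).append(fid)
        else:
            for fid in self.values.index:
                gene = self.probe_to_gene.get(str(fid))  # type: ignore[union-attr]
                if gene is not None:
                    gene_to_features.setdefault(gene, []).append(fid)
        self._gene_to_features = gene_to_features

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def features_for_genes(self, genes) -> list[str]:
        """All feature ids (probes or gene rows) mapping to the given symbols."""
        out: list[str] = []
        for gene in genes:
            out.extend(self._gene_to_features.get(normalize_symbol(gene), []))
        return out

    def genes_present(self, genes) -> set[str]:
        return {normalize_symbol(g) for g in genes} & set(self._gene_to_features)

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature_id")


def read_expression_tsv(
    path: str | Path,
    feature_kind: str = "gene",
    probe_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first column feature ids, header sample ids.

    Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values=df, feature_kind=feature_kind, probe_to_gene=probe_map)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_symbol) TSV into a map."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionError("probe map needs two columns: probe_id, gene_symbol")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    return {str(p): normalize_symbol(str(g)) for p, g in zip(probes, genes)}
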