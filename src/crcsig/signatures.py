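"""Gene-expression signature gene sets and GMT I/O.

A signature is a named collection of gene symbols split into up to four
components: up-regulated (UP), down-regulated (DOWN) and, for signatures
derived from presence/absence contrasts, "+inf" genes (detected only in the
perturbed state) and "-inf" genes (detected only in the control state).
Signatures are the unit of per-sample scoring (see :mod:`crcsig.scoring`).

GMT convention: one tab-separated line per gene set — name, description,
then gene symbols. Multi-component signatures are encoded as several lines
sharing a stem with suffixes ``_UP``, ``_DOWN``, ``_PLUSINF``, ``_MINUSINF``;
these are merged into a single :class:`GeneSignature` on read. Unsuffixed
lines become up-only signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import yaml

__all__ = [
    "GeneSignature",
    "SignatureRegistry",
    "SignatureError",
    "GMTParseError",
    "UnknownSignatureError",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "make_dasa_s",
]

_COMPONENT_SUFFIXES = {
    "_UP": "up_genes",
    "_DOWN": "down_genes",
    "_PLUSINF": "plus_inf_genes",
    "_MINUSINF": "minus_inf_genes",
}


class SignatureError(ValueError):
    """Invalid signature definition (empty UP set, overlapping components...)."""


class GMTParseError(SignatureError):
    """Malformed GMT content; carries the offending line number."""


class UnknownSignatureError(KeyError):
    """Requested signature name not present in the registry."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped of whitespace and upper-cased.

    Idempotent; no alias/HGNC resolution is attempted.
    """
    return symbol.strip().upper()


def _normalize_set(genes: Iterable[str], context: str) -> frozenset[str]:
    raw = [normalize_symbol(g) for g in genes if normalize_symbol(g)]
    out = frozenset(raw)
    if len(raw) != len(out):
        warnings.warn(f"duplicate gene symbols in {context} were deduplicated")
    return out


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with UP / DOWN / +inf / -inf components.

    Invariants enforced on construction: non-empty name, non-empty UP set,
    pairwise-disjoint components, symbols normalized (upper-case, stripped).
    """

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str] = frozenset()
    plus_inf_genes: frozenset[str] = frozenset()
    minus_inf_genes: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise SignatureError("signature name must be non-empty")
        for attr in ("up_genes", "down_genes", "plus_inf_genes", "minus_inf_genes"):
            object.__setattr__(
                self, attr, _normalize_set(getattr(self, attr), f"{self.name}.{attr}")
            )
        if not self.up_genes:
            raise SignatureError(f"signature {self.name!r}: up_genes must be non-empty")
        comps = [self.up_genes, self.down_genes, self.plus_inf_genes, self.minus_inf_genes]
        total = sum(len(c) for c in comps)
        if len(frozenset().union(*comps)) != total:
            raise SignatureError(
                f"signature {self.name!r}: component gene sets must be pairwise disjoint"
            )

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes | self.plus_inf_genes | self.minus_inf_genes

    @property
    def default_mode(self) -> str:
        """Scoring mode used when none is specified.

        Signatures with a DOWN component are scored as UP mean minus DOWN
        mean; up-only signatures (including those where only the UP genes
        are retained for scoring, e.g. SRC activation, Dasa-S) as the UP
        mean alone.
        """
        return "up_minus_down" if self.down_genes else "up_only"


@dataclass
class SignatureRegistry:
    """Ordered, name-unique collection of :class:`GeneSignature`."""

    signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            raise SignatureError("duplicate signature names in registry")
        self._by_name = {s.name: s for s in self.signatures}

    def add(self, sig: GeneSignature) -> None:
        if sig.name in self._by_name:
            raise SignatureError(f"signature {sig.name!r} already registered")
        self.signatures.append(sig)
        self._by_name[sig.name] = sig

    def __getitem__(self, name: str) -> GeneSignature:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownSignatureError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def to_yaml(self, path: str | Path) -> None:
        """Write a YAML manifest (names, component sizes, sources) for provenance."""
        manifest = [
            {
                "name": s.name,
                "source": s.source,
                "n_up": len(s.up_genes),
                "n_down": len(s.down_genes),
                "n_plus_inf": len(s.plus_inf_genes),
                "n_minus_inf": len(s.minus_inf_genes),
            }
            for s in self.signatures
        ]
        Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def _split_component(line_name: str) -> tuple[str, str]:
    for suffix, attr in _COMPONENT_SUFFIXES.items():
        if line_name.upper().endswith(suffix):
            return line_name[: -len(suffix)], attr
    return line_name, "up_genes"


def read_gmt(path: str | Path) -> SignatureRegistry:
    """Parse a GMT file into a registry, merging component-suffixed lines.

    Each line needs at least three tab-separated fields (name, description,
    one or more genes). Both ``\\n`` and ``\\r\\n`` line endings are accepted.
    """
    path = Path(path)
    partial: dict[str, dict[str, object]] = {}
    order: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            stem, component = _split_component(fields[0].strip())
            genes = _normalize_set(fields[2:], f"{path.name}:{lineno}")
            if stem not in partial:
                partial[stem] = {"source": fields[1].strip(), "components": {}}
                order.append(stem)
            comps: dict = partial[stem]["components"]  # type: ignore[assignment]
            if component in comps:
                raise GMTParseError(
                    f"{path.name}:{lineno}: duplicate component line for signature {stem!r}"
                )
            comps[component] = genes
    registry = SignatureRegistry()
    for stem in order:
        comps = partial[stem]["components"]  # type: ignore[assignment]
        registry.add(
            GeneSignature(
                name=stem,
                up_genes=comps.get("up_genes", frozenset()),
                down_genes=comps.get("down_genes", frozenset()),
                plus_inf_genes=comps.get("plus_inf_genes", frozenset()),
                minus_inf_genes=comps.get("minus_inf_genes", frozenset()),
                source=str(partial[stem]["source"]),
            )
        )
    return registry


def write_gmt(registry: SignatureRegistry, path: str | Path) -> None:
    """Serialize a registry to GMT; inverse of :func:`read_gmt` up to gene order."""
    lines: list[str] = []
    for sig in registry:
        desc = sig.source or "na"
        if sig.down_genes or sig.plus_inf_genes or sig.minus_inf_genes:
            for suffix, attr in _COMPONENT_SUFFIXES.items():
                genes = getattr(sig, attr)
                if genes:
                    lines.append("\t".join([sig.name + suffix, desc, *sorted(genes)]))
        else:
            lines.append("\t".join([sig.name, desc, *sorted(sig.up_genes)]))
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def make_dasa_s(six_gene_signature: GeneSignature) -> GeneSignature:
    """Reduce a dasatinib-sensitivity signature to its UP genes only.

    The published 6-gene dasatinib sensitivity signature carries five
    up-regulated genes (EPHA2, CAV1, CAV2, ANXA1, PTRF) and one
    down-regulated gene (IGFBP2); the DOWN gene is dropped because it is
    not predictive of SRC-inhibitor sensitivity in colorectal models.
    Returns a copy with the DOWN set emptied and ``_5GENE`` appended to the
    name; a signature with no DOWN genes is returned unchanged with a
    warning.
    """
    if not six_gene_signature.down_genes:
        warnings.warn(
            f"signature {six_gene_signature.name!r} has no DOWN genes; returning unchanged"
        )
        return six_gene_signature
    return replace(
        six_gene_signature,
        name=six_gene_signature.name + "_5GENE",
        down_genes=frozenset(),
    )
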