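"""Named gene collections with provenance.

A :class:`GeneSet` is the currency of every intersection in the pipeline:
the basic IH transcriptome list, the published proliferating/involuting
lists, the toxicological core, and the putative-biomarker sets are all
GeneSets.  Provenance notes record which stage produced or excluded each
member, so the final report can account for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


@dataclass
class GeneSet:
    """An ordered, duplicate-free collection of gene symbols.

    Parameters
    ----------
    name
        Non-empty label for the set (e.g. ``"basic_ih"``).
    genes
        Gene symbols; order is preserved, duplicates rejected.
    provenance
        Optional per-gene notes describing which stage produced (or, for
        excluded genes tracked separately, removed) the member.
    """

    name: str
    genes: tuple[str, ...] = ()
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        genes = tuple(self.genes)
        seen = set()
        for g in genes:
            if not g:
                raise ValueError(f"GeneSet {self.name!r} contains an empty symbol")
            if g in seen:
                raise ValueError(f"GeneSet {self.name!r} contains duplicate symbol {g!r}")
            seen.add(g)
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def intersect(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        """Order-preserving intersection (order of ``self``)."""
        keep = other.as_set()
        name = name or f"{self.name}&{other.name}"
        genes = tuple(g for g in self.genes if g in keep)
        prov = {g: f"in {self.name} and {other.name}" for g in genes}
        return GeneSet(name, genes, prov)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        name = name or f"{self.name}|{other.name}"
        genes = list(self.genes) + [g for g in other.genes if g not in set(self.genes)]
        return GeneSet(name, tuple(genes))

    def difference(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        drop = other.as_set()
        name = name or f"{self.name}-{other.name}"
        genes = tuple(g for g in self.genes if g not in drop)
        return GeneSet(name, genes, {g: self.provenance.get(g, "") for g in genes})


def geneset_from_iterable(name: str, genes: Iterable[str],
                          provenance: Mapping[str, str] | None = None) -> GeneSet:
    """Build a GeneSet, silently deduplicating while preserving first occurrence."""
    seen: dict[str, None] = {}
    for g in genes:
        g = str(g).strip()
        if g:
            seen.setdefault(g, None)
    prov = dict(provenance) if provenance else {}
    return GeneSet(name, tuple(seen), prov)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line plain-text gene list.

    Blank lines and ``#`` comments are ignored; duplicates are collapsed
    (published lists are deduplicated before intersection).
    """
    path = Path(path)
    symbols = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return geneset_from_iterable(name or path.stem, symbols)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file (name, description, genes...) into named GeneSets."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = geneset_from_iterable(parts[0], parts[2:])
    return sets


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gs.genes))
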