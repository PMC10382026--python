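"""Gene-set collections and the GMT file format."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import InputError

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene lists with an optional explicit universe.

    When no universe is given, the union of all member genes serves as
    the default universe for enrichment tests (callers may widen it with
    the submitted query list).
    """

    sets: dict[str, list[str]]
    universe: set[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise InputError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self) -> set[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def effective_universe(self, extra=()) -> set[str]:
        uni = set(self.universe) if self.universe is not None else self.genes()
        uni.update(extra)
        return uni

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            universe=self.universe,
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, 'name<TAB>description<TAB>genes...'."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise InputError(f"{path}: duplicate gene-set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "na") or "na"
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
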