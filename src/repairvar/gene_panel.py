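"""DNA-repair gene panel: membership after symbol normalization.

Gene symbols drift over time; a panel frozen years ago may list a symbol
that an annotator has since replaced. The panel therefore carries, for each
gene, its current symbol plus any outdated aliases, and membership testing
is case-insensitive over both (plus the stable gene identifier when both
sides have one). Matching is exact — no fuzzy matching, since a silently
wrong hit would corrupt the panel restriction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from .errors import PanelError
from .variants import AnnotatedVariant


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    aliases: frozenset[str] = frozenset()
    gene_id: Optional[str] = None

    def __post_init__(self):
        if not self.symbol:
            raise PanelError("empty panel gene symbol")
        if self.symbol in self.aliases:
            raise PanelError(f"{self.symbol}: symbol listed among its own aliases")


def _lines(source: Union[str, TextIO]) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    out = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def load_panel(
    panel_source: Union[str, TextIO],
    alias_source: Union[str, TextIO, None] = None,
) -> set[PanelGene]:
    """Load a panel file (one symbol per line, ``#`` comments) and an
    optional two-column old→current alias map.

    An alias pair updates the panel: if the current symbol is already a
    panel member the old symbol is attached as its alias; if instead the
    *old* symbol is what the panel lists, the entry is renamed to the
    current symbol, keeping the old one as an alias. Pairs touching no
    panel symbol are ignored.
    """
    symbols: list[str] = []
    gene_ids: dict[str, str] = {}
    for line in _lines(panel_source):
        parts = re.split(r"\t+", line)
        sym = parts[0].strip().upper()
        if len(parts) > 1 and parts[1].strip():
            gid = parts[1].strip()
            if sym in gene_ids and gene_ids[sym] != gid:
                raise PanelError(f"duplicate symbol {sym} with conflicting gene ids")
            gene_ids[sym] = gid
        if sym not in symbols:
            symbols.append(sym)

    aliases: dict[str, set[str]] = {s: set() for s in symbols}
    if alias_source is not None:
        for line in _lines(alias_source):
            parts = line.split("\t")
            if len(parts) != 2:
                raise PanelError(f"alias map line is not two columns: {line!r}")
            old, cur = parts[0].strip().upper(), parts[1].strip().upper()
            if cur in aliases:
                aliases[cur].add(old)
            elif old in aliases:  # panel still lists the outdated symbol
                idx = symbols.index(old)
                symbols[idx] = cur
                aliases[cur] = aliases.pop(old) | {old}
                if old in gene_ids:
                    gene_ids[cur] = gene_ids.pop(old)

    return {
        PanelGene(sym, frozenset(aliases[sym]) - {sym}, gene_ids.get(sym))
        for sym in symbols
    }


class PanelIndex:
    """Case-insensitive lookup structure over a panel (symbols, aliases, ids)."""

    def __init__(self, panel: Iterable[PanelGene]):
        self._by_symbol: dict[str, PanelGene] = {}
        self._by_id: dict[str, PanelGene] = {}
        for g in panel:
            self._by_symbol[g.symbol.upper()] = g
            for alias in g.aliases:
                self._by_symbol[alias.upper()] = g
            if g.gene_id:
                self._by_id[g.gene_id] = g

    def lookup(self, symbol: Optional[str] = None,
               gene_id: Optional[str] = None) -> Optional[PanelGene]:
        if symbol and symbol.upper() in self._by_symbol:
            return self._by_symbol[symbol.upper()]
        if gene_id and gene_id in self._by_id:
            return self._by_id[gene_id]
        return None


def in_panel(variant: AnnotatedVariant, panel: Iterable[PanelGene]) -> bool:
    """True iff the variant's gene symbol (or alias, case-insensitive) or
    stable gene id belongs to the panel."""
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    return index.lookup(variant.gene, variant.annotation.gene_id) is not None
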