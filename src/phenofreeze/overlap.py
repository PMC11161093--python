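"""Gene-set overlap testing with Fisher's exact test.

Tests whether one gene list (e.g. the differentially expressed genes
between phasic and sustained responders) is enriched for another (e.g. a
disorder-associated set) against an explicitly stated universe of
genes.  The universe is a required input and never inferred: the
hypergeometric p-value depends directly on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols, upper-cased on construction."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list: one symbol per line, ``#`` comments."""
    path = Path(path)
    symbols = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GeneSet.from_symbols(name or path.stem, symbols)


def combine_sets(sets: Sequence[GeneSet]) -> GeneSet:
    """Union of several gene sets (e.g. DEGs pooled across sexes)."""
    if not sets:
        raise ValueError("need at least one gene set")
    genes: frozenset[str] = frozenset()
    for s in sets:
        genes = genes | s.genes
    return GeneSet("+".join(s.name for s in sets), genes)


@dataclass
class OverlapResult:
    """2x2 overlap contingency table with Fisher's exact test results.

    Table layout: rows = in/out of set A, columns = in/out of set B,
    so ``table[0, 0]`` is the overlap.  ``odds_ratio`` is the sample
    odds ratio (a·d)/(b·c); when any cell is zero the Haldane correction
    adds 0.5 to all four cells.  ``p_value`` is the two-sided exact
    hypergeometric p.
    """

    set_a: str
    set_b: str
    universe_n: int
    table: np.ndarray
    overlap: int
    odds_ratio: float
    p_value: float
    flagged: bool = False


def fisher_overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Fisher's exact test of the overlap between two gene sets.

    Symbols outside the universe are dropped with a warning.  An empty
    (restricted) set gives overlap 0 and p = 1, flagged.
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    a_genes = set_a.genes & universe.genes
    b_genes = set_b.genes & universe.genes
    for s, kept in ((set_a, a_genes), (set_b, b_genes)):
        extra = s.genes - universe.genes
        if extra:
            warnings.warn(
                f"gene set {s.name!r}: {len(extra)} symbol(s) outside the "
                f"universe dropped (e.g. {sorted(extra)[:3]})", stacklevel=2)

    n = len(universe)
    a = len(a_genes & b_genes)
    b = len(a_genes) - a
    c = len(b_genes) - a
    d = n - a - b - c
    table = np.array([[a, b], [c, d]], dtype=int)

    if len(a_genes) == 0 or len(b_genes) == 0:
        warnings.warn("empty gene set after universe restriction; p = 1", stacklevel=2)
        return OverlapResult(set_a.name, set_b.name, n, table, a, _odds_ratio(table), 1.0,
                             flagged=True)

    _, p = sps.fisher_exact(table, alternative="two-sided")
    return OverlapResult(set_a.name, set_b.name, n, table, a, _odds_ratio(table), float(p))


def _odds_ratio(table: np.ndarray) -> float:
    a, b, c, d = (float(v) for v in table.ravel())
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)
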