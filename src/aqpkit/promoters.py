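"""Promoter scanning for stress-related cis-regulatory elements.

Scans 2000 bp upstream windows for every catalog consensus on both strands.
Coordinates are 0-based and always refer to the forward-strand leftmost
base of the matched substring; a minus-strand hit means the reverse
complement of that substring satisfies the consensus. An 'N' in the
promoter never matches any consensus symbol.
"""

from __future__ import annotations

import re

import pandas as pd

from .records import IUPAC_DNA, CreCatalog, CreHit, PromoterRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str) -> re.Pattern:
    # Character classes expand to concrete bases only, so a promoter 'N'
    # (missing data) can never match. Lookahead reports overlapping hits.
    body = "".join(
        sym if len(IUPAC_DNA[sym]) == 1 else f"[{IUPAC_DNA[sym]}]"
        for sym in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_promoter(promoter: PromoterRecord, catalog: CreCatalog) -> list:
    """All position/strand matches of every catalog element in one promoter.

    Hits are sorted by start, then element name, then strand (+ before -).
    """
    seq = promoter.sequence
    hits = []
    for name, consensus, both in catalog.elements:
        patterns = [("+", consensus)]
        if both:
            patterns.append(("-", reverse_complement(consensus)))
        for strand, pattern in patterns:
            for m in _iupac_regex(pattern).finditer(seq):
                hits.append(CreHit(
                    gene_id=promoter.gene_id, element=name,
                    start=m.start(), strand=strand, matched=m.group(1),
                ))
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


def scan_promoters(promoters, catalog: CreCatalog) -> list:
    """Scan a collection of promoters; concatenated hit list."""
    out = []
    for p in promoters:
        out.extend(scan_promoter(p, catalog))
    return out


def presence_matrix(hits, genes, catalog: CreCatalog) -> pd.DataFrame:
    """Boolean gene x element matrix: True iff >= 1 hit for the pair."""
    genes = list(genes)
    gene_set = set(genes)
    matrix = pd.DataFrame(False, index=genes, columns=list(catalog.names))
    for h in hits:
        if h.gene_id not in gene_set:
            raise ValueError(f"hit references unknown gene {h.gene_id!r}")
        matrix.loc[h.gene_id, h.element] = True
    matrix.index.name = "gene"
    return matrix


def count_genes_with_element(matrix: pd.DataFrame, elements) -> int:
    """Number of genes with >= 1 hit among the named element(s).

    ``elements`` may be a single name or an iterable (e.g. the wound pair
    WRE3 + WUN, counted as genes carrying at least one of the two).
    """
    if isinstance(elements, str):
        elements = [elements]
    elements = list(elements)
    unknown = [e for e in elements if e not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown element(s): {unknown}")
    return int(matrix[elements].any(axis=1).sum())


def hits_to_frame(hits) -> pd.DataFrame:
    """BED-like table (gene, start, end, element, strand, matched)."""
    return pd.DataFrame(
        [(h.gene_id, h.start, h.start + len(h.matched), h.element,
          h.strand, h.matched) for h in hits],
        columns=["gene", "start", "end", "element", "strand", "matched"],
    )
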