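"""Gene-structure statistics and Nei-Gojobori (1986) Ka/Ks estimation.

``gene_structure_stats`` summarises exon/intron counts and length extrema
over a cohort of gene models (introns are the gaps between consecutive
exons). ``kaks_ng86`` implements the NG86 counting method on a pair of
codon-aligned coding sequences: per-codon synonymous site fractions
(mutations to stop codons count as nonsynonymous), difference counting
averaged over minimal mutational pathways with stop-containing
intermediates excluded, and the Jukes-Cantor multiple-hit correction
applied to both proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .records import GeneModel, KaKsResult

_FORWARD = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _FORWARD[codon]


@dataclass(frozen=True)
class StructureStats:
    """Cohort-level exon/intron statistics with owning gene ids."""

    per_gene: dict  # gene_id -> {exon_count, intron_count, exon_lengths, intron_lengths}
    shortest_exon: tuple  # (gene_id, length)
    longest_exon: tuple
    shortest_intron: tuple | None  # None when the cohort has no introns
    longest_intron: tuple | None
    max_intron_count: tuple  # (gene_id, count)
    min_intron_count: tuple


def gene_structure_stats(models) -> StructureStats:
    """Exon/intron statistics over validated gene models.

    Extrema ties are broken deterministically by first gene id in input
    order.
    """
    models = list(models)
    if not models:
        raise ValueError("at least one gene model required")
    per_gene = {}
    exon_ext, intron_ext = [], []
    for m in models:
        if not isinstance(m, GeneModel):
            raise TypeError("expected GeneModel instances")
        per_gene[m.gene_id] = {
            "exon_count": len(m.exons),
            "intron_count": len(m.introns),
            "exon_lengths": m.exon_lengths,
            "intron_lengths": m.intron_lengths,
        }
        exon_ext.extend((m.gene_id, L) for L in m.exon_lengths)
        intron_ext.extend((m.gene_id, L) for L in m.intron_lengths)

    def _min(pairs):
        return min(pairs, key=lambda p: p[1]) if pairs else None

    def _max(pairs):
        return max(pairs, key=lambda p: p[1]) if pairs else None

    counts = [(m.gene_id, len(m.introns)) for m in models]
    return StructureStats(
        per_gene=per_gene,
        shortest_exon=_min(exon_ext),
        longest_exon=_max(exon_ext),
        shortest_intron=_min(intron_ext),
        longest_intron=_max(intron_ext),
        max_intron_count=_max(counts),
        min_intron_count=_min(counts),
    )


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (s; nonsynonymous = 3 - s).

    Each of the nine single-base neighbours contributes 1/3 of a site;
    neighbours that create a stop codon count as nonsynonymous.
    """
    aa = _translate(codon)
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1:]
            if neighbour not in _STOPS and _translate(neighbour) == aa:
                syn += 1
    return syn / 3.0


def _codon_diffs(c1: str, c2: str) -> tuple:
    """(syn, nonsyn) differences between two codons, pathway-averaged.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are dropped before averaging (if every
    pathway hits a stop, the average is taken over all of them).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathway_counts = []
    for order in permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in _STOPS:
                valid = False
                break
            if _translate(nxt) == _translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if valid:
            pathway_counts.append((syn, nonsyn))
    if not pathway_counts:  # every ordering hits a stop; fall back to all
        for order in permutations(diff_pos):
            current = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1:]
                if nxt not in _STOPS and _translate(nxt) == _translate(current):
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            pathway_counts.append((syn, nonsyn))
    n = len(pathway_counts)
    return (sum(p[0] for p in pathway_counts) / n,
            sum(p[1] for p in pathway_counts) / n)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction d = -3/4 ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(
            f"proportion {p:.3f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _check_cds(seq: str, label: str) -> None:
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length must be a multiple of 3")
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)} (no gaps allowed)")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for k, c in enumerate(codons[:-1]):
        if c in _STOPS:
            raise ValueError(f"{label}: internal stop codon {c} at codon {k}")
    if codons[-1] in _STOPS:
        raise ValueError(f"{label}: terminal stop codon not allowed in alignment")


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for a codon-aligned CDS pair.

    Site counts are averaged over both sequences; ``n_sites + s_sites``
    equals three times the codon count. The Ka/Ks ratio is exposed as
    ``result.ratio`` and is None (undefined) when Ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    _check_cds(cds_a, "first CDS")
    _check_cds(cds_b, "second CDS")
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]

    s_a = sum(_codon_sites(c) for c in codons_a)
    s_b = sum(_codon_sites(c) for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites

    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        ds, dn = _codon_diffs(ca, cb)
        sd += ds
        nd += dn

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KaKsResult(ka=ka, ks=ks, n_sites=n_sites, s_sites=s_sites,
                      n_diffs=nd, s_diffs=sd)
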