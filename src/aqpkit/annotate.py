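"""Motif-level annotation of aquaporin protein sequences.

Residue-level features (NPA triplets, ar/R selectivity filter, Froger
positions, SDP residues) are extracted by globally aligning a query to a
subfamily ``PositionTemplate`` and carrying the template's feature columns
through the alignment. Physicochemical properties (Mw, pI, GRAVY) follow
the ProtParam conventions via Biopython; transmembrane segments come from a
Kyte-Doolittle sliding-window heuristic (a deliberately simple stand-in for
HMM topology predictors, not expected to match their domain counts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .records import (
    CANONICAL_AA,
    WILDCARD,
    NpaMotif,
    PhyschemReport,
    PositionTemplate,
    ProteinRecord,
)

#: Degenerate loop-B/E triplet grammar: N-P followed by any of the observed
#: third-position variants (alanine plus the S/T/L/V/I substitutions).
NPA_PATTERN = re.compile(r"NP[ASTLVI]")

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_IDENTITY_FLOOR = 0.25


class LowConfidenceAlignment(ValueError):
    """Query/template identity fell below the configured floor."""

    def __init__(self, identity: float, floor: float):
        self.identity = identity
        self.floor = floor
        super().__init__(
            f"alignment identity {identity:.3f} below floor {floor:.3f}"
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two gapped strings plus its score."""

    a_gapped: str
    b_gapped: str
    score: float

    def identity(self) -> float:
        """Fraction of matching residues over columns aligned in both."""
        matches = aligned = 0
        for x, y in zip(self.a_gapped, self.b_gapped):
            if x != "-" and y != "-":
                aligned += 1
                if x == y:
                    matches += 1
        return matches / aligned if aligned else 0.0


def _blosum62_with_neutral_wildcard():
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    xi = m.alphabet.index(WILDCARD)
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


_MATRIX = _blosum62_with_neutral_wildcard()


def _check_protein(seq: str, label: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{label} must be non-empty")
    bad = set(seq) - CANONICAL_AA - {WILDCARD}
    if bad:
        raise ValueError(f"{label} contains non-canonical residues {sorted(bad)}")


def align_global(a: str, b: str, gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment under BLOSUM62.

    A gap of length k costs ``gap_open + gap_extend * (k - 1)``. The
    wildcard 'X' scores 0 against everything. Traceback ties are broken by
    the aligner's deterministic enumeration order (first optimal alignment).
    """
    _check_protein(a, "first sequence")
    _check_protein(b, "second sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(a_gapped=str(aln[0]), b_gapped=str(aln[1]),
                             score=aln.score)


def map_template_positions(
    query: ProteinRecord,
    template: PositionTemplate,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> dict:
    """Carry template feature columns through a query/reference alignment.

    Returns ``{feature_name: (query_index, residue) | None}``; ``None``
    marks columns that land on an alignment gap in the query. Raises
    ``LowConfidenceAlignment`` when identity over aligned columns is below
    ``identity_floor``.
    """
    aln = align_global(template.reference_sequence, query.sequence)
    identity = aln.identity()
    if identity < identity_floor:
        raise LowConfidenceAlignment(identity, identity_floor)

    # Walk the alignment once, recording query index per reference column.
    ref_to_query: dict = {}
    ri = qi = 0
    for rc, qc in zip(aln.a_gapped, aln.b_gapped):
        if rc != "-" and qc != "-":
            ref_to_query[ri] = qi
        if rc != "-":
            ri += 1
        if qc != "-":
            qi += 1

    out = {}
    for name, ref_pos in template.columns.items():
        qpos = ref_to_query.get(ref_pos)
        if qpos is None:
            out[name] = None
        else:
            out[name] = (qpos, query.sequence[qpos])
    return out


def find_npa_motifs(seq: str, template: PositionTemplate | None = None) -> list:
    """Locate the loop-B and loop-E NPA triplets (degenerate grammar).

    The sequence is scanned for N-P-[ASTLVI]; when fewer than two hits are
    found and a template is supplied, the template's NPA columns are mapped
    through an alignment to recover fully degenerate triplets (e.g. the SLV
    and SPA variants of XIP proteins). The first reported motif is labelled
    loop B, the second loop E; overlapping pairs are never reported.
    """
    starts = {m.start() for m in NPA_PATTERN.finditer(seq)}
    if len(starts) < 2 and template is not None:
        mapping = map_template_positions(ProteinRecord("query", seq), template)
        for motif in ("npa1", "npa2"):
            # Vote over the three columns: each mapped column implies a
            # triplet start; majority wins (single-column alignment slips
            # around fully substituted triplets are outvoted).
            candidates = []
            for i in (1, 2, 3):
                hit = mapping.get(f"{motif}_{i}")
                if hit is not None:
                    candidates.append(hit[0] - (i - 1))
            if candidates:
                best = max(set(candidates),
                           key=lambda c: (candidates.count(c), -c))
                if 0 <= best and best + 3 <= len(seq):
                    starts.add(best)
    motifs = []
    last_end = -1
    for start in sorted(starts):
        if start < last_end:
            continue  # drop overlaps deterministically (keep earlier motif)
        motifs.append(start)
        last_end = start + 3
        if len(motifs) == 2:
            break
    return [
        NpaMotif(loop=loop, start=s, triplet=seq[s:s + 3])
        for loop, s in zip("BE", motifs)
    ]


def compute_gravy(seq: str, skip_wildcard: bool = False) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _check_protein(seq)
    if WILDCARD in seq:
        if not skip_wildcard:
            raise ValueError(
                "sequence contains wildcard 'X'; pass skip_wildcard=True to "
                "average over canonical residues only"
            )
        seq = seq.replace(WILDCARD, "")
        if not seq:
            raise ValueError("no canonical residues left after skipping wildcards")
    return ProteinAnalysis(seq).gravy()


def compute_mw(seq: str, skip_wildcard: bool = False) -> float:
    """Average-mass molecular weight in kDa (residue masses + one water)."""
    _check_protein(seq)
    if WILDCARD in seq:
        if not skip_wildcard:
            raise ValueError("sequence contains wildcard 'X'")
        seq = seq.replace(WILDCARD, "")
        if not seq:
            raise ValueError("no canonical residues left after skipping wildcards")
    return ProteinAnalysis(seq).molecular_weight() / 1000.0


def compute_pi(seq: str, skip_wildcard: bool = False) -> float:
    """Isoelectric point (Bjellqvist pKa set, bisection on net charge)."""
    _check_protein(seq)
    if WILDCARD in seq:
        if not skip_wildcard:
            raise ValueError("sequence contains wildcard 'X'")
        seq = seq.replace(WILDCARD, "")
        if not seq:
            raise ValueError("no canonical residues left after skipping wildcards")
    return ProteinAnalysis(seq).isoelectric_point()


def charge_at_pH(seq: str, ph: float) -> float:
    """Net charge of the peptide at a given pH (same model as compute_pi)."""
    return ProteinAnalysis(seq).charge_at_pH(ph)


def predict_tm_segments(seq: str, window: int = 19,
                        threshold: float = 1.6) -> list:
    """Hydropathy-based transmembrane segments.

    Maximal runs of window-centred mean Kyte-Doolittle hydropathy >= the
    threshold, reported as 0-based inclusive (start, end) spans over the
    full windows; overlapping spans are merged.
    """
    _check_protein(seq)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    if WILDCARD in seq:
        raise ValueError("TM prediction requires canonical residues only")
    half = window // 2
    values = [KYTE_DOOLITTLE[c] for c in seq]
    # Rolling window means over all valid centres.
    total = sum(values[:window])
    means = [total / window]
    for i in range(window, len(seq)):
        total += values[i] - values[i - window]
        means.append(total / window)
    # means[j] is centred at residue j + half.
    segments = []
    run_start = None
    for j, m in enumerate(means):
        if m >= threshold:
            if run_start is None:
                run_start = j
        elif run_start is not None:
            segments.append((run_start, j - 1 + window - 1))
            run_start = None
    if run_start is not None:
        segments.append((run_start, len(means) - 1 + window - 1))
    merged = []
    for s, e in segments:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [tuple(seg) for seg in merged]


def annotate_protein(record: ProteinRecord,
                     template: PositionTemplate | None = None,
                     tm_window: int = 19, tm_threshold: float = 1.6) -> dict:
    """Full JSON-ready annotation for one protein.

    Includes NPA motifs (0-based indices), the template-mapped ar/R,
    Froger and per-substrate SDP residues when a template is given, and
    the physicochemical report.
    """
    motifs = find_npa_motifs(record.sequence, template)
    features: dict = {}
    if template is not None:
        mapping = map_template_positions(record, template)
        for name, hit in mapping.items():
            features[name] = (
                None if hit is None else {"index": hit[0], "residue": hit[1]}
            )
    physchem = PhyschemReport(
        mw_kda=compute_mw(record.sequence, skip_wildcard=True),
        pi=compute_pi(record.sequence, skip_wildcard=True),
        gravy=compute_gravy(record.sequence, skip_wildcard=True),
        tm_segments=tuple(
            predict_tm_segments(record.sequence, tm_window, tm_threshold)
        ) if WILDCARD not in record.sequence else (),
    )
    return {
        "id": record.id,
        "length": len(record),
        "npa_motifs": [
            {"loop": m.loop, "start": m.start, "triplet": m.triplet}
            for m in motifs
        ],
        "features": features,
        "physchem": {
            "mw_kda": physchem.mw_kda,
            "pi": physchem.pi,
            "gravy": physchem.gravy,
            "tm_segments": [list(s) for s in physchem.tm_segments],
        },
    }
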