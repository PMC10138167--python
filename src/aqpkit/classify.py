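"""Subfamily classification, SDP substrate inference and distance trees.

The subfamily caller is a small decision tree over the Froger P1-P5 and
ar/R signatures; on the curated 28-member roster it fires without ever
needing its nearest-reference fallback. The substrate engine counts, per
protein and substrate, the SDP positions whose residue falls outside the
substrate's allowed set; a protein is classified as a putative transporter
when the count does not exceed the active tolerance (strict 0 by default,
per-substrate overrides reproduce the prose-style "classified despite a
substitution" calls).
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .annotate import align_global
from .records import SdpVector, SubfamilyCall, SubstrateCall, SubstrateConsensus
from .templates import SUBFAMILY_SIGNATURES


def classify_subfamily(froger: str, arR: str, name: str = "") -> SubfamilyCall:
    """Assign a subfamily from the Froger P1-P5 (and, for the fallback, ar/R).

    Decision tree: P5 != W -> NIP; P4=F,P5=W -> PIP when P1 in {E,Q}, XIP
    when P2=C; P4=Y,P5=W -> TIP when P1 in {T,V}, otherwise SIP. Signatures
    not resolved by the tree fall back to the nearest subfamily reference
    (Hamming distance over Froger + ar/R), flagged ``confidence="fallback"``.
    """
    if len(froger) != 5:
        raise ValueError(f"froger signature must have length 5, got {froger!r}")
    if len(arR) != 4:
        raise ValueError(f"ar/R signature must have length 4, got {arR!r}")
    p1, p2, _, p4, p5 = froger
    path = []
    if p5 != "W":
        path.append("P5!=W")
        return SubfamilyCall(name, "NIP", tuple(path), "signature")
    path.append("P5=W")
    if p4 == "F":
        path.append("P4=F")
        if p1 in {"E", "Q"}:
            path.append("P1 in {E,Q}")
            return SubfamilyCall(name, "PIP", tuple(path), "signature")
        if p2 == "C":
            path.append("P2=C")
            return SubfamilyCall(name, "XIP", tuple(path), "signature")
    elif p4 == "Y":
        path.append("P4=Y")
        if p1 in {"T", "V"}:
            path.append("P1 in {T,V}")
            return SubfamilyCall(name, "TIP", tuple(path), "signature")
        path.append("P1 not in {T,V}")
        return SubfamilyCall(name, "SIP", tuple(path), "signature")
    # Nearest-reference fallback, deterministic on (distance, subfamily order).
    path.append("unresolved->nearest-reference")
    best = None
    for subfamily, sig in SUBFAMILY_SIGNATURES.items():
        d = sum(a != b for a, b in zip(froger, sig["froger"]))
        d += sum(a != b for a, b in zip(arR, sig["arR"]))
        if best is None or d < best[0]:
            best = (d, subfamily)
    return SubfamilyCall(name, best[1], tuple(path), "fallback")


def count_sdp_mismatches(vector: SdpVector,
                         consensus: SubstrateConsensus) -> tuple:
    """(count, positions) of SDPs whose residue is outside the allowed set.

    Positions are 1-based SDP numbers, in SDP order.
    """
    if vector.substrate_context != consensus.substrate:
        raise ValueError(
            f"vector context {vector.substrate_context!r} does not match "
            f"consensus substrate {consensus.substrate!r}"
        )
    positions = tuple(
        i for i, (residue, allowed) in enumerate(
            zip(vector.residues, consensus.allowed), start=1
        )
        if residue not in allowed
    )
    return len(positions), positions


def infer_substrates(vectors, consensi, tolerance=0) -> list:
    """Substrate calls for every vector against its substrate's consensus.

    ``tolerance`` is either a single integer in [0, 9] or a mapping
    substrate -> integer; a vector is ``classified`` when its mismatch
    count is <= the tolerance for its substrate. The mismatch positions
    are always reported, so lenient "prose-mode" calls stay auditable.
    """
    by_substrate = {c.substrate: c for c in consensi}
    calls = []
    for v in vectors:
        consensus = by_substrate.get(v.substrate_context)
        if consensus is None:
            raise ValueError(f"no consensus for substrate {v.substrate_context!r}")
        tol = tolerance.get(v.substrate_context, 0) if isinstance(
            tolerance, dict) else tolerance
        if not 0 <= tol <= 9:
            raise ValueError("tolerance must lie in [0, 9]")
        n, positions = count_sdp_mismatches(v, consensus)
        calls.append(SubstrateCall(
            protein=v.protein,
            substrate=v.substrate_context,
            mismatches=n,
            mismatch_positions=positions,
            classified=n <= tol,
        ))
    return calls


def distance_matrix(records) -> tuple:
    """Pairwise p-distances (1 - identity over aligned non-gap columns).

    Returns (ids, symmetric ndarray).
    """
    ids = [r.id for r in records]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_global(records[i].sequence, records[j].sequence)
            d[i, j] = d[j, i] = 1.0 - aln.identity()
    return ids, d


def neighbor_joining(ids, matrix) -> str:
    """Saitou-Nei neighbor joining; returns the unrooted tree as Newick.

    Exact on additive distance matrices. Requires at least three taxa.
    """
    matrix = np.asarray(matrix, dtype=float)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = nj(DistanceMatrix(matrix, ids))
    return str(tree).strip()
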