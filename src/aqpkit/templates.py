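"""Per-subfamily position templates for alignment-based motif annotation.

Plant aquaporin literature reports the NPA, ar/R, Froger and SDP residues of
a protein relative to a curated multiple alignment, never as absolute
coordinates. This module supplies that missing anchor: a synthetic reference
sequence per subfamily whose feature columns are known exactly. Queries are
annotated by aligning them to the reference of their (putative) subfamily
and carrying each column through the alignment.

The reference backbone mirrors the canonical MIP fold ordering: the ar/R H2
residue upstream of the loop-B NPA, then H5, Froger P1, the loop-E NPA,
LE1/LE2, Froger P2-P5 and, further toward the C-terminus, the nine SDP
columns of each substrate context. Filler positions deliberately contain no
asparagine or proline, so a degenerate N-P-x triplet can only ever occur at
the planted NPA columns.
"""

from __future__ import annotations

from .records import SUBSTRATES, PositionTemplate

# Filler alphabet: canonical residues minus N and P (see module docstring).
FILLER_ALPHABET = "GASTLVIEQKRDHFWYCM"

# Reference spacer lengths between consecutive feature blocks, in backbone
# order. The generator jitters these; the template uses them verbatim.
SPACERS = {
    "nterm": 20, "post_arR_H2": 18, "post_npa1": 12, "post_arR_H5": 9,
    "post_froger_P1": 7, "post_npa2": 7, "post_arR_LE1": 3,
    "post_arR_LE2": 10, "post_froger_tail": 12, "pre_sdp_block": 4,
    "cterm": 15,
}

# Representative signature residues per subfamily, taken from the curated
# roster and SDP tables (first allowed residue of the consensus where the
# subfamily has no tabulated member in a substrate context).
_CONSENSUS_FIRST = {
    "ammonia": "FKFVADAEA",
    "boric_acid": "TIHPEIIAA",
    "co2": "IICAIDWDW",
    "h2o2": "AALAIHFAP",
    "silicic_acid": "CFAHGKREA",
    "urea": "HPFALAGGN",
}

SUBFAMILY_SIGNATURES = {
    "PIP": {
        "npa1": "NPA", "npa2": "NPA", "arR": "FHTR", "froger": "QSAFW",
        "sdp": {"ammonia": _CONSENSUS_FIRST["ammonia"],
                "boric_acid": "TIHPEILTP", "co2": "VITAIDWDW",
                "h2o2": "AGVFIQFVP",
                "silicic_acid": _CONSENSUS_FIRST["silicic_acid"],
                "urea": "HPFFLPGGN"},
    },
    "NIP": {
        "npa1": "NPA", "npa2": "NPA", "arR": "WVAR", "froger": "FSAYI",
        "sdp": {"ammonia": _CONSENSUS_FIRST["ammonia"],
                "boric_acid": "VIHPELMAP", "co2": _CONSENSUS_FIRST["co2"],
                "h2o2": "SALLVIYVP", "silicic_acid": "SFVHGNRSN",
                "urea": "HPIALPGSN"},
    },
    "TIP": {
        "npa1": "NPA", "npa2": "NPA", "arR": "HIGR", "froger": "TSAYW",
        "sdp": {"ammonia": "TLILATHPV",
                "boric_acid": _CONSENSUS_FIRST["boric_acid"],
                "co2": _CONSENSUS_FIRST["co2"], "h2o2": "AALVINYVP",
                "silicic_acid": _CONSENSUS_FIRST["silicic_acid"],
                "urea": "HPFALPGSN"},
    },
    "SIP": {
        "npa1": "NPS", "npa2": "NPA", "arR": "AVPN", "froger": "MAAYW",
        "sdp": dict(_CONSENSUS_FIRST),
    },
    "XIP": {
        "npa1": "NPV", "npa2": "NPA", "arR": "ITVR", "froger": "VCAFW",
        "sdp": {"ammonia": _CONSENSUS_FIRST["ammonia"],
                "boric_acid": "TIHPEITTV", "co2": _CONSENSUS_FIRST["co2"],
                "h2o2": "AGLVVHFVP",
                "silicic_acid": _CONSENSUS_FIRST["silicic_acid"],
                "urea": "HPFAVGGGN"},
    },
}

FEATURE_NAMES = (
    ["npa1_1", "npa1_2", "npa1_3", "npa2_1", "npa2_2", "npa2_3",
     "arR_H2", "arR_H5", "arR_LE1", "arR_LE2"]
    + [f"froger_P{i}" for i in range(1, 6)]
    + [f"{sub}_sdp{i}" for sub in SUBSTRATES for i in range(1, 10)]
)


def feature_blocks(signature: dict) -> list:
    """Backbone order of (spacer_key, [(feature_name, residue), ...]) blocks.

    A residue of '-' marks a feature deliberately absent from the sequence
    (the missing-residue sentinel used for one ar/R position).
    """
    sig = signature
    blocks = [
        ("nterm", [("arR_H2", sig["arR"][0])]),
        ("post_arR_H2", [(f"npa1_{i+1}", sig["npa1"][i]) for i in range(3)]),
        ("post_npa1", [("arR_H5", sig["arR"][1])]),
        ("post_arR_H5", [("froger_P1", sig["froger"][0])]),
        ("post_froger_P1", [(f"npa2_{i+1}", sig["npa2"][i]) for i in range(3)]),
        ("post_npa2", [("arR_LE1", sig["arR"][2])]),
        ("post_arR_LE1", [("arR_LE2", sig["arR"][3])]),
        ("post_arR_LE2", [(f"froger_P{i}", sig["froger"][i - 1])
                          for i in range(2, 6)]),
    ]
    spacer = "post_froger_tail"
    for sub in SUBSTRATES:
        blocks.append((spacer, [(f"{sub}_sdp{i+1}", sig["sdp"][sub][i])
                                for i in range(9)]))
        spacer = "pre_sdp_block"
    blocks.append(("cterm", []))
    return blocks


def build_sequence(signature: dict, spacer_lengths: dict,
                   filler_at) -> tuple:
    """Assemble a sequence from a signature and explicit spacer lengths.

    ``filler_at(k)`` supplies the k-th filler residue. Returns the sequence
    and the {feature_name: 0-based position} map (features whose residue is
    the '-' sentinel are skipped and absent from the map).
    """
    chars: list = []
    columns: dict = {}
    k = 0
    for spacer_key, features in feature_blocks(signature):
        for _ in range(spacer_lengths[spacer_key]):
            chars.append(filler_at(k))
            k += 1
        for name, residue in features:
            if residue == "-":
                continue
            columns[name] = len(chars)
            chars.append(residue)
    return "".join(chars), columns


def _subfamily_filler(subfamily: str):
    # Fixed, subfamily-offset filler cycle keeps references distinguishable
    # while remaining fully deterministic.
    offset = list(SUBFAMILY_SIGNATURES).index(subfamily)

    def filler(k: int) -> str:
        return FILLER_ALPHABET[(k * 7 + offset * 3) % len(FILLER_ALPHABET)]

    return filler


def reference_layout(subfamily: str, signature: dict | None = None) -> list:
    """Backbone blocks [(spacer_string, [(feature, residue), ...]), ...].

    The spacer strings are the subfamily reference filler; generators
    mutate them (indels/substitutions) while keeping feature residues
    plantable, so synthetic queries stay alignable to the reference.
    """
    sig = signature or SUBFAMILY_SIGNATURES[subfamily]
    filler = _subfamily_filler(subfamily)
    blocks = []
    k = 0
    for spacer_key, features in feature_blocks(sig):
        n = SPACERS[spacer_key]
        spacer = "".join(filler(k + i) for i in range(n))
        k += n
        blocks.append((spacer, list(features)))
    return blocks


def build_template(subfamily: str) -> PositionTemplate:
    """Deterministic reference template for one subfamily."""
    sig = SUBFAMILY_SIGNATURES[subfamily]
    seq, columns = build_sequence(sig, SPACERS, _subfamily_filler(subfamily))
    return PositionTemplate(
        subfamily=subfamily, reference_sequence=seq, columns=columns
    )


def default_templates() -> dict:
    """One packaged template per subfamily."""
    return {sf: build_template(sf) for sf in SUBFAMILY_SIGNATURES}
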