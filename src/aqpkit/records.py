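"""Domain types shared across the toolkit.

Everything here is a small validated dataclass: protein and promoter
sequences, the curated family roster, SDP residue vectors and per-substrate
consensus sets, gene models and the cis-element catalog. Validation happens
in ``__post_init__`` so a constructed object can be trusted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
WILDCARD = "X"
SUBFAMILIES = ("PIP", "NIP", "TIP", "SIP", "XIP")
SUBSTRATES = ("ammonia", "boric_acid", "co2", "h2o2", "silicic_acid", "urea")
DNA_ALPHABET = set("ACGTN")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ValidationError(ValueError):
    """A record violated one of its invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (canonical residues, optional 'X')."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA - {WILDCARD}
        if bad:
            raise ValidationError(
                f"{self.id}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PromoterRecord:
    """An upstream promoter window (<= 2000 bp, uppercase A/C/G/T/N)."""

    gene_id: str
    sequence: str

    MAX_LENGTH = 2000

    def __post_init__(self) -> None:
        if len(self.sequence) > self.MAX_LENGTH:
            raise ValidationError(
                f"{self.gene_id}: promoter longer than {self.MAX_LENGTH} bp"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.gene_id}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RosterEntry:
    """One curated family member with its motif and physicochemical fields.

    ``arR`` may contain '-' as an explicit missing-residue sentinel
    (one NIP lacks the second ar/R residue). ``tdp`` and the two
    localization fields are lookup-only annotations carried through
    from upstream predictors, never recomputed here.
    """

    name: str
    subfamily: str
    aa_length: int
    npa1: str
    npa2: str
    arR: str
    froger: str
    mw: float
    ip: float
    kaks: float
    gravy: float
    tdp: int
    localization_wp: str
    localization_pp: str

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValidationError(f"{self.name}: unknown subfamily {self.subfamily!r}")
        if self.subfamily not in self.name:
            raise ValidationError(
                f"{self.name}: name prefix inconsistent with subfamily {self.subfamily}"
            )
        if self.aa_length <= 0:
            raise ValidationError(f"{self.name}: aa_length must be positive")
        for label, val, n in (("npa1", self.npa1, 3), ("npa2", self.npa2, 3),
                              ("arR", self.arR, 4), ("froger", self.froger, 5)):
            if len(val) != n:
                raise ValidationError(
                    f"{self.name}: {label} must have length {n}, got {val!r}"
                )
        if self.kaks < 0:
            raise ValidationError(f"{self.name}: Ka/Ks must be >= 0")


@dataclass(frozen=True)
class SdpVector:
    """Nine observed residues (SDP1..SDP9) of one protein in one substrate context."""

    protein: str
    substrate_context: str
    residues: tuple

    def __post_init__(self) -> None:
        if self.substrate_context not in SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate_context!r}")
        if len(self.residues) != 9:
            raise ValidationError(
                f"{self.protein}/{self.substrate_context}: expected 9 residues, "
                f"got {len(self.residues)}"
            )
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"{self.protein}/{self.substrate_context}: non-canonical {sorted(bad)}"
            )


@dataclass(frozen=True)
class SubstrateConsensus:
    """Allowed residue sets at SDP1..SDP9 for one transported substrate."""

    substrate: str
    allowed: tuple  # 9 frozensets of residues

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if len(self.allowed) != 9:
            raise ValidationError(
                f"{self.substrate}: expected 9 allowed sets, got {len(self.allowed)}"
            )
        for i, s in enumerate(self.allowed, start=1):
            if not s:
                raise ValidationError(f"{self.substrate}: SDP{i} allowed set empty")
            bad = set(s) - CANONICAL_AA
            if bad:
                raise ValidationError(
                    f"{self.substrate}: SDP{i} non-canonical {sorted(bad)}"
                )


@dataclass(frozen=True)
class GeneModel:
    """Exon coordinates of one gene (1-based inclusive, GFF3 convention)."""

    gene_id: str
    strand: str
    exons: tuple  # ordered (start, end) pairs
    utr5: tuple | None = None
    utr3: tuple | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"{self.gene_id}: exon start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end

    @property
    def introns(self) -> tuple:
        """Gaps between consecutive exons, as 1-based inclusive pairs."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def exon_lengths(self) -> tuple:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def intron_lengths(self) -> tuple:
        return tuple(e - s + 1 for s, e in self.introns)


@dataclass(frozen=True)
class CreCatalog:
    """Named IUPAC consensus strings for promoter cis-element scanning."""

    elements: tuple  # of (name, consensus, both_strands)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.elements]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate element names in catalog")
        for name, consensus, _ in self.elements:
            bad = set(consensus) - set(IUPAC_DNA)
            if bad:
                raise ValidationError(
                    f"element {name}: non-IUPAC symbols {sorted(bad)}"
                )

    @property
    def names(self) -> tuple:
        return tuple(name for name, _, _ in self.elements)

    def consensus(self, name: str) -> str:
        for n, c, _ in self.elements:
            if n == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class CreHit:
    """One strand-aware match of a catalog element in a promoter.

    ``start`` is the 0-based leftmost position on the forward strand,
    regardless of strand; a minus-strand hit means the reverse complement
    of the matched substring satisfies the consensus.
    """

    gene_id: str
    element: str
    start: int
    strand: str
    matched: str


@dataclass(frozen=True)
class NpaMotif:
    """A (possibly degenerate) NPA triplet located in loop B or loop E."""

    loop: str  # "B" or "E"
    start: int  # 0-based
    triplet: str


@dataclass(frozen=True)
class PositionTemplate:
    """A subfamily reference sequence with named feature columns.

    ``columns`` maps feature names (npa1_1.., arR_H2, froger_P1..,
    <substrate>_sdp1..) to 0-based positions in ``reference_sequence``.
    Query annotation works by globally aligning the query to the
    reference and carrying each column through the alignment.
    """

    subfamily: str
    reference_sequence: str
    columns: dict = field(compare=False)

    def __post_init__(self) -> None:
        n = len(self.reference_sequence)
        for name, pos in self.columns.items():
            if not (0 <= pos < n):
                raise ValidationError(f"template column {name} out of range")


@dataclass(frozen=True)
class PhyschemReport:
    """Computed physicochemical summary for one protein."""

    mw_kda: float
    pi: float
    gravy: float
    tm_segments: tuple

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValidationError("molecular weight must be positive")
        if not (0 < self.pi < 14):
            raise ValidationError("isoelectric point must lie in (0, 14)")
        prev_end = None
        for s, e in self.tm_segments:
            if prev_end is not None and s <= prev_end:
                raise ValidationError("TM segments overlap or are unsorted")
            prev_end = e


@dataclass(frozen=True)
class SubfamilyCall:
    """Result of the Froger/ar-R signature decision tree."""

    name: str
    subfamily: str
    rule_path: tuple
    confidence: str  # "signature" or "fallback"

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValidationError(f"unknown subfamily {self.subfamily!r}")
        if not self.rule_path:
            raise ValidationError("rule_path must record at least one test")
        if self.confidence not in {"signature", "fallback"}:
            raise ValidationError("confidence must be 'signature' or 'fallback'")


@dataclass(frozen=True)
class SubstrateCall:
    """Mismatch count of one SDP vector against one substrate consensus."""

    protein: str
    substrate: str
    mismatches: int
    mismatch_positions: tuple  # of ints in 1..9 (SDP numbering)
    classified: bool

    def __post_init__(self) -> None:
        if self.mismatches != len(self.mismatch_positions):
            raise ValidationError("mismatch count disagrees with positions")


@dataclass(frozen=True)
class KaKsResult:
    """Nei-Gojobori substitution-rate estimates for one codon-aligned pair."""

    ka: float
    ks: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks = 0 (undefined)."""
        if self.ks == 0:
            return None
        return self.ka / self.ks
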