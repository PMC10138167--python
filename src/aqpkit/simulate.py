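"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed and returns
machine-readable ground truth alongside the data, so every downstream
module has a planted-truth recovery test. Defaults mirror the study
conditions this toolkit targets: 28-member aquaporin rosters, 2000 bp
promoter windows, 1-5 exons per gene, codon pairs dominated by synonymous
change (purifying selection), and Ct tables with three biological x two
technical replicates and Gaussian cycle noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import load_roster, load_sdp_tables
from .promoters import reverse_complement, scan_promoter
from .records import (
    IUPAC_DNA,
    CreCatalog,
    GeneModel,
    PromoterRecord,
    ProteinRecord,
)
from .templates import (
    FILLER_ALPHABET,
    SUBFAMILY_SIGNATURES,
    reference_layout,
)
from .expression import CtTable

_BASES = "ACGT"


class GeneratorError(RuntimeError):
    """A generator could not satisfy its constraints within its budget."""


# ---------------------------------------------------------------------------
# Proteins with planted motif features
# ---------------------------------------------------------------------------

def _member_signature(entry, sdp_vectors) -> dict:
    """Signature dict for one roster entry (roster + SDP-table residues)."""
    sig = {
        "npa1": entry.npa1, "npa2": entry.npa2, "arR": entry.arR,
        "froger": entry.froger,
        "sdp": dict(SUBFAMILY_SIGNATURES[entry.subfamily]["sdp"]),
    }
    for v in sdp_vectors:
        if v.protein == entry.name:
            sig["sdp"][v.substrate_context] = "".join(v.residues)
    return sig


def _mutate_spacer(spacer: str, rng, indel_frac: float,
                   sub_frac: float) -> str:
    """Apply random substitutions and net indels to a backbone spacer.

    Mutated residues stay within the N/P-free filler alphabet so no
    spurious degenerate NPA triplet can arise.
    """
    chars = list(spacer)
    n_sub = int(round(sub_frac * len(chars)))
    for i in rng.choice(len(chars), size=min(n_sub, len(chars)),
                        replace=False) if chars else []:
        chars[i] = FILLER_ALPHABET[rng.integers(len(FILLER_ALPHABET))]
    delta = int(rng.integers(-int(indel_frac * len(chars)),
                             int(indel_frac * len(chars)) + 1)) if chars else 0
    if delta < 0:
        for i in sorted(rng.choice(len(chars), size=-delta, replace=False),
                        reverse=True):
            del chars[i]
    elif delta > 0:
        for _ in range(delta):
            pos = int(rng.integers(0, len(chars) + 1))
            chars.insert(pos, FILLER_ALPHABET[rng.integers(len(FILLER_ALPHABET))])
    return "".join(chars)


def generate_aqp_proteins(members=None, seed: int = 0,
                          indel_frac: float = 0.15,
                          sub_frac: float = 0.15) -> tuple:
    """Synthetic aquaporin-like proteins with planted feature residues.

    ``members`` is a list of (name, signature-dict) pairs; by default the
    packaged 28-member roster supplies names and signatures (NPA/ar-R/
    Froger from the roster, SDP residues from the SDP table where
    tabulated). Each sequence is the subfamily template backbone with
    member feature residues planted and the inter-feature spacers mutated
    (substitutions plus net indels), so queries diverge from the reference
    while staying alignable; spacers never contain N or P, so degenerate
    NPA triplets occur only at planted columns. A feature residue of '-'
    (missing-residue sentinel) is skipped and absent from the truth map.

    Returns (records, truth) where truth maps name -> {feature: (0-based
    position, residue)}.
    """
    rng = np.random.default_rng(seed)
    if members is None:
        roster = load_roster()
        _, vectors = load_sdp_tables()
        members = [(e.name, _member_signature(e, vectors)) for e in roster]
    records, truth = [], {}
    for name, sig in members:
        subfamily = next(
            (sf for sf in SUBFAMILY_SIGNATURES if sf in name), None
        ) or "PIP"
        chars: list = []
        columns: dict = {}
        for spacer, features in reference_layout(subfamily, sig):
            chars.extend(_mutate_spacer(spacer, rng, indel_frac, sub_frac))
            for feat, residue in features:
                if residue == "-":
                    continue
                columns[feat] = len(chars)
                chars.append(residue)
        seq = "".join(chars)
        records.append(ProteinRecord(id=name, sequence=seq))
        truth[name] = {feat: (pos, seq[pos]) for feat, pos in columns.items()}
    return records, truth


# ---------------------------------------------------------------------------
# Promoters with planted cis-element instances
# ---------------------------------------------------------------------------

def _instantiate(consensus: str, rng) -> str:
    return "".join(
        sym if len(IUPAC_DNA[sym]) == 1
        else IUPAC_DNA[sym][rng.integers(len(IUPAC_DNA[sym]))]
        for sym in consensus
    )


def _motif_free_background(length: int, catalog: CreCatalog, rng,
                           max_rounds: int = 60) -> str:
    """Uniform A/C/G/T background with no catalog motif on either strand.

    Rejection sampling: spans covering residual hits are redrawn until the
    scan comes back empty.
    """
    seq = list(rng.choice(list(_BASES), size=length))
    for _ in range(max_rounds):
        hits = scan_promoter(
            PromoterRecord(gene_id="bg", sequence="".join(seq)), catalog
        )
        if not hits:
            return "".join(seq)
        for h in hits:
            for i in range(h.start, h.start + len(h.matched)):
                seq[i] = _BASES[rng.integers(4)]
    raise GeneratorError(
        "background rejection sampling exceeded its retry budget; "
        "shorten the window or prune the catalog"
    )


def generate_promoters(presence: pd.DataFrame, catalog: CreCatalog,
                       seed: int = 0, length: int = 2000,
                       max_retries: int = 40) -> tuple:
    """Promoter set realising a given gene x element presence matrix.

    One concrete instance of each present element is planted per gene at a
    seeded random offset and strand over a motif-free background; after
    planting, the promoter is rescanned and accepted only if its scanned
    presence row equals the requested row (junction-spawned or colliding
    matches trigger a retry).

    Returns (records, truth) where truth maps gene -> list of
    (element, start, strand, planted_substring).
    """
    unknown = [c for c in presence.columns if c not in catalog.names]
    if unknown:
        raise ValueError(f"presence matrix has non-catalog elements: {unknown}")
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for gene, row in presence.iterrows():
        wanted = [e for e in presence.columns if row[e]]
        for _ in range(max_retries):
            background = _motif_free_background(length, catalog, rng)
            seq = list(background)
            placed = []
            occupied: list = []
            ok = True
            for element in wanted:
                instance = _instantiate(catalog.consensus(element), rng)
                strand = "+" if rng.integers(2) == 0 else "-"
                planted = instance if strand == "+" else reverse_complement(instance)
                L = len(planted)
                for _ in range(200):
                    start = int(rng.integers(0, length - L + 1))
                    if all(start + L <= s or start >= e for s, e in occupied):
                        break
                else:
                    ok = False
                    break
                occupied.append((start, start + L))
                seq[start:start + L] = planted
                placed.append((element, start, strand, planted))
            if not ok:
                continue
            promoter = PromoterRecord(gene_id=gene, sequence="".join(seq))
            scanned = {h.element for h in scan_promoter(promoter, catalog)}
            if scanned == set(wanted):
                records.append(promoter)
                truth[gene] = placed
                break
        else:
            raise GeneratorError(
                f"could not realise presence row for {gene!r} within the "
                "retry budget"
            )
    return records, truth


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def generate_gene_models(n_genes: int = 28, seed: int = 0,
                         exon_counts=(1, 5), exon_length=(33, 800),
                         intron_length=(80, 3500), spacing: int = 5000) -> tuple:
    """Random single-transcript gene models laid head-to-tail on one contig.

    Exon counts span the observed range (single-exon genes up to five
    exons / four introns). Returns (models, truth) where truth records the
    planted exon/intron lengths per gene.
    """
    rng = np.random.default_rng(seed)
    models, truth = [], {}
    cursor = 1
    for g in range(n_genes):
        gene_id = f"synthgene{g + 1:02d}"
        n_exons = int(rng.integers(exon_counts[0], exon_counts[1] + 1))
        exons = []
        pos = cursor
        e_lens, i_lens = [], []
        for k in range(n_exons):
            el = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((pos, pos + el - 1))
            e_lens.append(el)
            pos += el
            if k < n_exons - 1:
                il = int(rng.integers(intron_length[0], intron_length[1] + 1))
                i_lens.append(il)
                pos += il
        strand = "+" if rng.integers(2) == 0 else "-"
        models.append(GeneModel(gene_id=gene_id, strand=strand,
                                exons=tuple(exons)))
        truth[gene_id] = {"exon_lengths": tuple(e_lens),
                          "intron_lengths": tuple(i_lens)}
        cursor = pos + spacing
    return models, truth


# ---------------------------------------------------------------------------
# Codon-aligned CDS pairs
# ---------------------------------------------------------------------------

from .evolution import _STOPS, _translate  # noqa: E402  (shared genetic code)


def _random_codon(rng) -> str:
    while True:
        c = "".join(_BASES[rng.integers(4)] for _ in range(3))
        if c not in _STOPS:
            return c


def _single_change(codon: str, rng, synonymous: bool) -> str | None:
    """A one-base variant of the codon with the requested effect, or None."""
    options = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            if (_translate(alt) == _translate(codon)) == synonymous:
                options.append(alt)
    if not options:
        return None
    return options[rng.integers(len(options))]


def generate_cds_pair(n_codons: int = 300, n_syn: int = 15, n_nonsyn: int = 3,
                      seed: int = 0) -> tuple:
    """One codon-aligned CDS pair with planted substitution counts.

    Exactly ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous single-base
    changes are planted in distinct codons (no multi-hit codons, so the
    planted counts are exactly the NG86 observed differences). The default
    change mix is synonymous-dominated, emulating purifying selection.

    Returns (cds_a, cds_b, truth) with truth = {"syn": ..., "nonsyn": ...}.
    """
    if n_syn + n_nonsyn > n_codons:
        raise ValueError("more planted changes than codons")
    rng = np.random.default_rng(seed)
    changed: dict = {}
    codons = []
    # Draw codons until enough support each requested change type.
    budget = 50 * n_codons
    need = [(True, n_syn), (False, n_nonsyn)]
    plan: list = []
    for synonymous, count in need:
        plan.extend([synonymous] * count)
    plan = [plan[i] for i in rng.permutation(len(plan))]
    for i in range(n_codons):
        want = plan[i] if i < len(plan) else None
        for _ in range(budget):
            c = _random_codon(rng)
            if want is None:
                codons.append((c, c))
                break
            alt = _single_change(c, rng, synonymous=want)
            if alt is not None:
                codons.append((c, alt))
                break
        else:
            raise GeneratorError("could not draw a codon supporting the change")
    codons = [codons[i] for i in rng.permutation(len(codons))]
    a = "".join(c for c, _ in codons)
    b = "".join(c for _, c in codons)
    return a, b, {"syn": n_syn, "nonsyn": n_nonsyn}


def generate_cds_pairs(n_pairs: int = 20, seed: int = 0, **kwargs) -> list:
    """Independent CDS pairs; list of (cds_a, cds_b, truth)."""
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n_pairs)
    return [generate_cds_pair(seed=int(s), **kwargs) for s in seeds]


# ---------------------------------------------------------------------------
# Ct tables with planted fold-changes
# ---------------------------------------------------------------------------

def generate_ct_table(log2_fold_changes: pd.DataFrame, calibrator: str,
                      seed: int = 0, noise_sd: float = 0.2,
                      n_bio: int = 3, n_tech: int = 2,
                      efficiencies: dict | None = None,
                      reference_gene: str = "RPII",
                      not_detected=()) -> tuple:
    """A replicated Ct table realising planted log2 fold-changes.

    ``log2_fold_changes`` is genes x samples (the calibrator column must be
    all zeros). Per gene, a baseline calibrator Ct is drawn in [22, 28);
    each sample's true Ct is baseline - log2FC / log2(E); every
    biological x technical replicate adds Gaussian noise of ``noise_sd``
    cycles. The reference gene is constant (Ct 20) across samples, plus
    noise. Cells listed in ``not_detected`` are emitted as missing.

    Returns (CtTable, truth) with truth the input fold-change frame.
    """
    fc = log2_fold_changes
    if calibrator not in fc.columns:
        raise ValueError(f"calibrator {calibrator!r} not among samples")
    if not np.allclose(fc[calibrator].to_numpy(dtype=float), 0.0):
        raise ValueError("calibrator column of the fold-change table must be 0")
    efficiencies = dict(efficiencies or {})
    rng = np.random.default_rng(seed)
    nd = set(not_detected)
    rows = []
    base_ct = {g: float(rng.uniform(22, 28)) for g in fc.index}
    for gene in list(fc.index) + [reference_gene]:
        e = efficiencies.get(gene, 2.0)
        for sample in fc.columns:
            if gene == reference_gene:
                true_ct = 20.0
            else:
                true_ct = base_ct[gene] - float(fc.loc[gene, sample]) / np.log2(e)
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    if (gene, sample) in nd:
                        ct = np.nan
                    else:
                        ct = true_ct + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append((gene, sample, b, t, ct))
    data = pd.DataFrame(rows, columns=["gene", "sample", "bio_rep",
                                       "tech_rep", "ct"])
    table = CtTable(data=data, reference_gene=reference_gene,
                    efficiencies=efficiencies)
    return table, fc


# ---------------------------------------------------------------------------
# Hydropathy-block proteins for TM-segment recovery
# ---------------------------------------------------------------------------

def generate_tm_protein(n_blocks: int = 2, block_len: int = 23,
                        gap_len: int = 30, seed: int = 0) -> tuple:
    """A protein of hydrophobic blocks separated by hydrophilic linkers.

    Returns (sequence, truth) where truth is the list of 0-based inclusive
    (start, end) spans of the planted hydrophobic blocks.
    """
    rng = np.random.default_rng(seed)
    hydrophobic = "ILVF"
    hydrophilic = "DEKRQS"
    parts = []
    spans = []
    pos = 0

    def _stretch(alphabet, n):
        return "".join(alphabet[rng.integers(len(alphabet))] for _ in range(n))

    parts.append(_stretch(hydrophilic, gap_len))
    pos += gap_len
    for k in range(n_blocks):
        spans.append((pos, pos + block_len - 1))
        parts.append(_stretch(hydrophobic, block_len))
        pos += block_len
        parts.append(_stretch(hydrophilic, gap_len))
        pos += gap_len
    return "".join(parts), spans
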