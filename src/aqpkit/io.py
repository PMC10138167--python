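"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython, GFF3 through gffutils, tabular fixtures
through pandas. The packaged fixtures (family roster, SDP tables,
cis-element catalog and presence lists) are exposed through the
``load_packaged_*`` helpers.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CreCatalog,
    GeneModel,
    PromoterRecord,
    ProteinRecord,
    RosterEntry,
    SdpVector,
    SubstrateConsensus,
    ValidationError,
)

_ROSTER_COLUMNS = [
    "name", "subfamily", "aa_length", "npa1", "npa2", "arR", "froger",
    "mw", "ip", "kaks", "gravy", "tdp", "localization_wp", "localization_pp",
]


def _packaged(name: str) -> Path:
    return Path(resources.files("aqpkit").joinpath("data", name))


def read_fasta(path, kind: str = "protein") -> list:
    """Read a FASTA file into ``ProteinRecord`` or ``PromoterRecord`` objects.

    Sequences are uppercased; record order is preserved; duplicate ids are
    an error. ``kind`` selects the record type ("protein" or "promoter").
    """
    if kind not in {"protein", "promoter"}:
        raise ValueError(f"kind must be 'protein' or 'promoter', got {kind!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if kind == "protein":
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        else:
            records.append(PromoterRecord(gene_id=rec.id, sequence=seq))
    if not records:
        warnings.warn(f"no records found in {path}", stacklevel=2)
    return records


def write_fasta(records, path) -> None:
    """Write protein or promoter records to FASTA (one line per sequence)."""
    seqs = []
    for r in records:
        rid = r.id if isinstance(r, ProteinRecord) else r.gene_id
        seqs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def load_roster(path=None) -> list:
    """Load the curated family roster TSV (defaults to the packaged fixture)."""
    path = _packaged("roster.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"roster missing columns: {sorted(missing)}")
    entries = []
    names = set()
    for i, row in df.iterrows():
        if row["name"] in names:
            raise ValidationError(f"duplicate roster name {row['name']!r}")
        names.add(row["name"])
        try:
            entries.append(RosterEntry(
                name=row["name"],
                subfamily=row["subfamily"],
                aa_length=int(row["aa_length"]),
                npa1=row["npa1"],
                npa2=row["npa2"],
                arR=row["arR"],
                froger=row["froger"],
                mw=float(row["mw"]),
                ip=float(row["ip"]),
                kaks=float(row["kaks"]),
                gravy=float(row["gravy"]),
                tdp=int(row["tdp"]),
                localization_wp=row["localization_wp"],
                localization_pp=row["localization_pp"],
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"roster row {i} ({row['name']}): {exc}") from exc
    return entries


def load_sdp_tables(path=None) -> tuple:
    """Load the SDP fixture: (consensus list, member vector list).

    The TSV mixes ``role=consensus`` rows (slash-separated allowed sets)
    with ``role=member`` rows (single residues per position).
    """
    path = _packaged("sdp_table.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    sdp_cols = [f"sdp{i}" for i in range(1, 10)]
    missing = {"role", "substrate", "aquaporin", *sdp_cols} - set(df.columns)
    if missing:
        raise ValidationError(f"SDP table missing columns: {sorted(missing)}")
    consensi, vectors = [], []
    for i, row in df.iterrows():
        try:
            if row["role"] == "consensus":
                allowed = tuple(
                    frozenset(row[c].split("/")) for c in sdp_cols
                )
                consensi.append(SubstrateConsensus(
                    substrate=row["substrate"], allowed=allowed,
                ))
            elif row["role"] == "member":
                vectors.append(SdpVector(
                    protein=row["aquaporin"],
                    substrate_context=row["substrate"],
                    residues=tuple(row[c] for c in sdp_cols),
                ))
            else:
                raise ValidationError(f"unknown role {row['role']!r}")
        except ValidationError as exc:
            raise ValidationError(f"SDP table row {i}: {exc}") from exc
    return consensi, vectors


def load_cre_catalog(path=None) -> CreCatalog:
    """Load a cis-element catalog YAML (defaults to the packaged catalog)."""
    path = _packaged("cre_catalog.yaml") if path is None else path
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    elements = tuple(
        (e["name"], str(e["consensus"]).upper(), bool(e.get("both_strands", True)))
        for e in raw["elements"]
    )
    return CreCatalog(elements=elements)


def load_presence_fixture(path=None) -> pd.DataFrame:
    """Load the packaged gene x element presence matrix as a boolean frame."""
    path = _packaged("cre_presence.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
    return df.astype(bool)


def read_gff3(path) -> list:
    """Read gene models from GFF3; exons grouped per gene, sorted by start."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        )
        utrs5 = [(f.start, f.end)
                 for f in db.children(gene, featuretype="five_prime_UTR")]
        utrs3 = [(f.start, f.end)
                 for f in db.children(gene, featuretype="three_prime_UTR")]
        models.append(GeneModel(
            gene_id=gene.id,
            strand=gene.strand,
            exons=tuple(exons),
            utr5=utrs5[0] if utrs5 else None,
            utr3=utrs3[0] if utrs3 else None,
        ))
    return models


def write_gff3(models, path, seqid: str = "chr1") -> None:
    """Write gene models (gene + mRNA + exon features) to a GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gstart = m.exons[0][0]
            gend = m.exons[-1][1]
            fh.write(f"{seqid}\taqpkit\tgene\t{gstart}\t{gend}\t.\t{m.strand}\t."
                     f"\tID={m.gene_id}\n")
            mrna = f"{m.gene_id}.t1"
            fh.write(f"{seqid}\taqpkit\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t."
                     f"\tID={mrna};Parent={m.gene_id}\n")
            for k, (s, e) in enumerate(m.exons, start=1):
                fh.write(f"{seqid}\taqpkit\texon\t{s}\t{e}\t.\t{m.strand}\t."
                         f"\tID={mrna}.exon{k};Parent={mrna}\n")
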