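"""Readers and writers for the formats the pipeline touches.

CDS FASTA, GenBank flat files (CDS + tRNA features), tabular tRNA counts,
and generic TSV/JSON result tables.  GenBank parsing is delegated to
Biopython, which resolves join()/complement() locations; coordinates are
1-based inclusive on disk and 0-based half-open in memory, as usual.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

from Bio import SeqIO

from mitocub.codon_core import to_rna

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTURYSWKMBDHVN")

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}


@dataclass
class GeneRecord:
    gene_id: str
    genome_id: str
    organelle: str
    sequence: str  # uppercase DNA/RNA, as read
    source: str = "fasta"
    flags: list[str] = field(default_factory=list)


@dataclass
class TrnaCountRow:
    anticodon: str  # RNA 3-mer, 5'->3'; "NNN" when unknown
    amino_acid: str  # three-letter code
    copy_number: int


def read_cds_fasta(path: str | Path, genome_id: str, organelle: str) -> list[GeneRecord]:
    """Read one CDS per FASTA entry; the first header token is the gene id.

    Duplicate ids get a deterministic ``_2``, ``_3``... suffix (warned).
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"{path}: entry {entry.id!r} has non-nucleotide characters {sorted(bad)}"
            )
        gene_id = entry.id
        seen[gene_id] = seen.get(gene_id, 0) + 1
        if seen[gene_id] > 1:
            gene_id = f"{gene_id}_{seen[gene_id]}"
            logger.warning("%s: duplicate gene id %r renamed to %r", path, entry.id, gene_id)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                organelle=organelle,
                sequence=seq,
                source="fasta",
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_cds_fasta(records: list[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_ANTICODON_SEQ = re.compile(r"seq\s*:\s*([ACGTUacgtu]{3})")
_ANTICODON_BARE = re.compile(r"\b([ACGTUacgtu]{3})\b")


def _parse_anticodon(qualifiers: dict) -> str | None:
    for key in ("anticodon", "note"):
        for value in qualifiers.get(key, []):
            m = _ANTICODON_SEQ.search(value)
            if m:
                return to_rna(m.group(1))
            if key == "anticodon":
                m = _ANTICODON_BARE.search(value)
                if m:
                    return to_rna(m.group(1))
    return None


def _parse_trna_aa(qualifiers: dict) -> str:
    for value in qualifiers.get("product", []):
        m = re.search(r"tRNA[-_ ]([A-Za-z]{3})", value)
        if m:
            return m.group(1).capitalize()
    return "Xaa"


def extract_from_genbank(
    path: str | Path, genome_id: str | None = None, organelle: str = "mito"
) -> tuple[list[GeneRecord], list[TrnaCountRow], dict]:
    """Extract CDS records, tRNA copy numbers and summary stats from GenBank.

    CDS locations are resolved by Biopython (join/complement honoured, exons
    concatenated in annotation order, minus strand reverse-complemented).
    A CDS whose extracted length is not divisible by 3 is kept but flagged
    ``length_not_multiple_of_3`` and warned about, not fatal.  tRNA features
    lacking a parsable anticodon are counted under anticodon ``NNN``.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    trna_agg: dict[tuple[str, str], int] = {}
    n_cds = n_trna = n_rrna = 0
    total_len = 0
    gc_count = 0
    gid = genome_id
    seen: dict[str, int] = {}

    any_record = False
    for record in SeqIO.parse(str(path), "genbank"):
        any_record = True
        if len(record.seq) == 0:
            raise ValueError(f"{path}: record {record.id} has no sequence block")
        gid = gid or record.id
        seq_str = str(record.seq).upper()
        total_len += len(seq_str)
        gc_count += sum(b in "GCgc" for b in seq_str)
        for feat in record.features:
            if feat.type == "CDS":
                n_cds += 1
                raw = feat.qualifiers.get("gene") or feat.qualifiers.get(
                    "locus_tag"
                ) or feat.qualifiers.get("product") or [f"cds_{n_cds}"]
                base_id = raw[0].replace(" ", "_")
                seen[base_id] = seen.get(base_id, 0) + 1
                gene_id = base_id if seen[base_id] == 1 else f"{base_id}_{seen[base_id]}"
                cds_seq = str(feat.extract(record.seq)).upper()
                flags = []
                if len(cds_seq) % 3 != 0:
                    flags.append("length_not_multiple_of_3")
                    logger.warning(
                        "%s: CDS %s length %d not divisible by 3", path, gene_id, len(cds_seq)
                    )
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        genome_id=gid,
                        organelle=organelle,
                        sequence=cds_seq,
                        source="genbank",
                        flags=flags,
                    )
                )
            elif feat.type == "tRNA":
                n_trna += 1
                anticodon = _parse_anticodon(feat.qualifiers)
                aa = _parse_trna_aa(feat.qualifiers)
                if anticodon is None:
                    logger.warning("%s: tRNA-%s feature with unknown anticodon", path, aa)
                    anticodon = "NNN"
                trna_agg[(anticodon, aa)] = trna_agg.get((anticodon, aa), 0) + 1
            elif feat.type == "rRNA":
                n_rrna += 1
    if not any_record:
        raise ValueError(f"{path}: no GenBank records found")

    trna_rows = [
        TrnaCountRow(anticodon=ac, amino_acid=aa, copy_number=n)
        for (ac, aa), n in sorted(trna_agg.items())
    ]
    summary = {
        "genome_id": gid,
        "length": total_len,
        "gc": gc_count / total_len if total_len else math.nan,
        "n_cds": n_cds,
        "n_trna": n_trna,
        "n_rrna": n_rrna,
    }
    return genes, trna_rows, summary


def read_trna_tsv(path: str | Path) -> list[TrnaCountRow]:
    """Read tRNA counts from a TSV with columns anticodon, amino_acid, copy_number."""
    rows: list[TrnaCountRow] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty tRNA count table")
    header = body[0].rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for name in ("anticodon", "amino_acid", "copy_number"):
        if name not in idx:
            raise ValueError(f"{path}: missing column {name!r}")
    for ln in body[1:]:
        parts = ln.rstrip("\n").split("\t")
        anticodon = to_rna(parts[idx["anticodon"]])
        copy_number = int(parts[idx["copy_number"]])
        if copy_number < 1:
            raise ValueError(f"{path}: copy_number must be >= 1, got {copy_number}")
        rows.append(
            TrnaCountRow(
                anticodon=anticodon,
                amino_acid=parts[idx["amino_acid"]],
                copy_number=copy_number,
            )
        )
    return rows


def _row_to_dict(row) -> dict:
    if is_dataclass(row):
        return asdict(row)
    if isinstance(row, dict):
        return dict(row)
    raise TypeError(f"unsupported row type {type(row)!r}")


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return "nan" if math.isnan(v) else f"{v:.6g}"
    if isinstance(v, (list, tuple)):
        return ";".join(str(x) for x in v)
    return str(v)


def write_table(rows: list, path: str | Path, format: str = "tsv", columns: list[str] | None = None) -> None:
    """Write homogeneous rows (dicts or dataclasses) as TSV or JSON.

    Column order follows the first row (or ``columns``); floats are written
    at 6 significant digits in TSV.  An empty row list yields a header-only
    file (TSV) or an empty JSON array.
    """
    dicts = [_row_to_dict(r) for r in rows]
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for d in dicts:
                fh.write("\t".join(_format_value(d.get(c, "")) for c in columns) + "\n")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dicts, fh, indent=2, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")
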