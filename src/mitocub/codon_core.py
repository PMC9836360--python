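"""Genetic-code tables, synonymous-family construction, and codon counting.

Codons are represented internally as uppercase RNA 3-mers (``AUG``); DNA
input is transcribed on read.  Amino acids use one-letter codes with ``*``
for stop.  Two code tables are registered by default: ``standard`` (NCBI
translation table 1) and ``mold_mito`` (table 4; UGA reads Trp, AUA stays
Ile), and arbitrary tables can be loaded from a plain-text file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

RNA_BASES = "ACGU"
COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: all 64 RNA codons in lexicographic order (the canonical column order)
ALL_CODONS = tuple(
    "".join(c) for c in itertools.product(RNA_BASES, RNA_BASES, RNA_BASES)
)

REGISTERED_CODES = {"standard": 1, "mold_mito": 4}


class CodonUsageError(ValueError):
    """Raised on malformed coding sequences or inconsistent codon counts."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class FamilyPolicy:
    """How synonymous families are formed for RSCU.

    split_sixfold: analyse Leu/Ser/Arg as a fourfold plus a twofold
        sub-family (sub-families share the first two codon bases).
    exclude_nondegenerate: drop single-codon families (Met, Trp under the
        standard code) from RSCU vectors.

    ENc always uses unsplit amino-acid families regardless of this policy.
    """

    split_sixfold: bool = True
    exclude_nondegenerate: bool = True


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table plus derived synonymous-family structure.

    degeneracy_classes maps family size k to the tuple of unsplit families
    (each a tuple of codons) of that size; enc_max is the theoretical ENc
    upper bound (the number of sense codons).
    """

    code_id: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64 or set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError(
                f"genetic code {self.code_id!r} must map exactly the 64 RNA codons"
            )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != "*")

    @property
    def enc_max(self) -> int:
        return len(self.sense_codons)

    def families(self, policy: FamilyPolicy | None = None) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by a stable family id.

        Unsplit families are keyed by amino acid (``L``); split sixfold
        sub-families by amino acid + shared prefix (``L_CU``, ``L_UU``).
        """
        by_aa: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa == "*":
                continue
            by_aa.setdefault(aa, []).append(codon)

        if policy is None or not policy.split_sixfold:
            return {aa: tuple(sorted(cods)) for aa, cods in sorted(by_aa.items())}

        out: dict[str, tuple[str, ...]] = {}
        for aa, cods in sorted(by_aa.items()):
            if len(cods) <= 4:
                out[aa] = tuple(sorted(cods))
                continue
            boxes: dict[str, list[str]] = {}
            for c in cods:
                boxes.setdefault(c[:2], []).append(c)
            # merge boxes sharing a prefix into fourfold/twofold sub-families
            for prefix, sub in sorted(boxes.items()):
                out[f"{aa}_{prefix}"] = tuple(sorted(sub))
        return out

    @property
    def degeneracy_classes(self) -> dict[int, tuple[tuple[str, ...], ...]]:
        classes: dict[int, list[tuple[str, ...]]] = {}
        for fam in self.families().values():
            classes.setdefault(len(fam), []).append(fam)
        return {k: tuple(v) for k, v in sorted(classes.items())}

    def family_of(self, codon: str, policy: FamilyPolicy | None = None) -> tuple[str, ...]:
        for fam in self.families(policy).values():
            if codon in fam:
                return fam
        raise KeyError(f"{codon} is not a sense codon under code {self.code_id!r}")


def build_genetic_code(code_id: str | int | Path = "standard") -> GeneticCode:
    """Build a GeneticCode from a registered name, an NCBI table id, or a file.

    A user table file holds one ``codon<TAB>amino-acid`` pair per line
    (``#`` comments allowed); codons may be DNA or RNA, amino acids are
    one-letter codes with ``*`` (or the word STOP) for stop codons.
    """
    if isinstance(code_id, int):
        table_id, name = code_id, f"ncbi_{code_id}"
    elif str(code_id) in REGISTERED_CODES:
        name = str(code_id)
        table_id = REGISTERED_CODES[name]
    elif Path(str(code_id)).is_file():
        return _read_code_file(Path(str(code_id)))
    else:
        raise ValueError(
            f"unknown genetic code {code_id!r}: expected one of "
            f"{sorted(REGISTERED_CODES)}, an NCBI table id, or a table file"
        )
    try:
        table = CodonTable.unambiguous_rna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table id {table_id}") from exc
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(code_id=name, codon_to_aa=mapping)


def _read_code_file(path: Path) -> GeneticCode:
    mapping: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split()[:2]
        aa = "*" if aa.upper() == "STOP" else aa
        mapping[to_rna(codon)] = aa
    if set(mapping) != set(ALL_CODONS):
        missing = sorted(set(ALL_CODONS) - set(mapping))
        raise ValueError(
            f"code table {path} does not cover all 64 codons "
            f"(missing {missing[:4]}{'...' if len(missing) > 4 else ''})"
        )
    return GeneticCode(code_id=path.stem, codon_to_aa=mapping)


@dataclass
class CodonCounts:
    """Integer codon counts for one gene (or a per-genome pool)."""

    gene_id: str
    genome_id: str
    organelle: str
    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0
    code_id: str = "standard"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n_codons:
            raise CodonUsageError(
                f"{self.gene_id}: counts sum to {total}, expected n_codons={self.n_codons}"
            )
        if any(v < 0 for v in self.counts.values()):
            raise CodonUsageError(f"{self.gene_id}: negative codon count")


def count_codons(
    seq: str,
    code: GeneticCode,
    gene_id: str = "gene",
    genome_id: str = "genome",
    organelle: str = "mito",
) -> CodonCounts:
    """Count sense codons in a coding sequence.

    A single terminal stop codon is silently trimmed.  Codons containing
    any non-ACGU character are skipped and tallied in ``n_skipped``.  An
    internal stop codon is a hard error (frame problem upstream).
    """
    rna = to_rna(str(seq))
    if len(rna) % 3 != 0:
        raise CodonUsageError(
            f"{gene_id}: sequence length {len(rna)} is not divisible by 3"
        )
    if not rna:
        raise CodonUsageError(f"{gene_id}: empty sequence")
    codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    n_skipped = 0
    for i, codon in enumerate(codons):
        if any(b not in RNA_BASES for b in codon):
            n_skipped += 1
            continue
        if code.codon_to_aa[codon] == "*":
            raise CodonUsageError(
                f"{gene_id}: internal stop codon {codon} at codon position {i + 1}"
            )
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(
        gene_id=gene_id,
        genome_id=genome_id,
        organelle=organelle,
        counts=counts,
        n_codons=len(codons) - n_skipped,
        n_skipped=n_skipped,
        code_id=code.code_id,
    )


def pool_counts(gene_counts: list[CodonCounts], gene_id: str = "pooled") -> CodonCounts:
    """Element-wise sum of per-gene counts into one per-genome pool."""
    if not gene_counts:
        raise CodonUsageError("cannot pool an empty list of codon counts")
    genomes = {c.genome_id for c in gene_counts}
    codes = {c.code_id for c in gene_counts}
    if len(genomes) > 1:
        raise CodonUsageError(f"cannot pool counts from mixed genomes: {sorted(genomes)}")
    if len(codes) > 1:
        raise CodonUsageError(f"cannot pool counts under mixed codes: {sorted(codes)}")
    pooled: dict[str, int] = {}
    for c in gene_counts:
        for codon, n in c.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    first = gene_counts[0]
    return CodonCounts(
        gene_id=gene_id,
        genome_id=first.genome_id,
        organelle=first.organelle,
        counts=pooled,
        n_codons=sum(c.n_codons for c in gene_counts),
        n_skipped=sum(c.n_skipped for c in gene_counts),
        code_id=first.code_id,
    )
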