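import numpy as np
import pytest

from mitocub.codon_core import CodonCounts, build_genetic_code


@pytest.fixture(scope="session")
def standard_code():
    return build_genetic_code("standard")


@pytest.fixture(scope="session")
def mold_code():
    return build_genetic_code("mold_mito")


def make_counts(counts: dict, gene_id="gene", genome_id="genome", code_id="standard"):
    return CodonCounts(
        gene_id=gene_id,
        genome_id=genome_id,
        organelle="mito",
        counts=dict(counts),
        n_codons=sum(counts.values()),
        code_id=code_id,
    )


def random_counts(rng: np.random.Generator, code, n_codons=300, gene_id="rand"):
    """Random codon counts over the code's sense codons."""
    sense = code.sense_codons
    draws = rng.multinomial(n_codons, np.ones(len(sense)) / len(sense))
    counts = {c: int(n) for c, n in zip(sense, draws) if n}
    return make_counts(counts, gene_id=gene_id, code_id=code.code_id)


# --- tiny hand-written GenBank fixture -------------------------------------
# 60 bp sequence; one forward CDS 1..9, one spliced CDS join(10..15,19..24),
# one complement CDS complement(25..33), two tRNAs sharing anticodon UGC and
# one with an anticodon only in /note, plus one rRNA.
GENBANK_FIXTURE = """\
LOCUS       TESTMITO                  60 bp    DNA     circular     01-JAN-2024
DEFINITION  Synthetic test mitogenome.
ACCESSION   TESTMITO
FEATURES             Location/Qualifiers
     source          1..60
     CDS             1..9
                     /gene="fwd1"
     CDS             join(10..15,19..24)
                     /gene="spliced1"
     CDS             complement(25..33)
                     /gene="rev1"
     tRNA            34..36
                     /product="tRNA-Ala"
                     /anticodon="(pos:34..36,aa:Ala,seq:tgc)"
     tRNA            37..39
                     /product="tRNA-Ala"
                     /anticodon="(pos:37..39,aa:Ala,seq:tgc)"
     tRNA            40..42
                     /product="tRNA-Phe"
                     /note="anticodon seq:gaa"
     rRNA            43..60
                     /product="small subunit ribosomal RNA"
ORIGIN
        1 atggcagcat tcaaagggac ctaaggcctg cattttgcag cgaaaaaaaa aaaaaaaaaa
//
"""

GENBANK_SEQ = "ATGGCAGCATTCAAAGGGACCTAAGGCCTGCATTTTGCAGCGAAAAAAAAAAAAAAAAAA"


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "test.gb"
    path.write_text(GENBANK_FIXTURE)
    return path
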