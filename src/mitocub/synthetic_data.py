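"""Synthetic gene sets and tRNAomes with controlled statistical structure.

The gene generator draws amino acids uniformly over degenerate families and
picks synonymous codons with probability proportional to
``m(c) * exp(beta * g * wi_c)``: m(c) is a mutational weight whose
third-position GC probability is set per gene, g is the gene's expression
weight, and beta the selection strength.  beta = 0 is exactly the pure
mutational-bias model, so neutral calibration runs need no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitocub.codon_core import COMPLEMENT, CodonCounts, GeneticCode, build_genetic_code
from mitocub.trna_selection import TRNAome, WiVector, compute_wi, default_s_vector
from mitocub.wobble import WobbleRules


@dataclass
class SyntheticSpec:
    """Parameters of one simulated genome (a set of genes)."""

    n_genes: int
    gene_length: int  # codons per gene
    gc3_target: float | list[float] = 0.5  # scalar or one value per gene
    beta: float = 0.0
    expression: list[float] | None = None  # per-gene weights; None = all 1
    code_id: str = "standard"
    seed: int = 0
    genome_id: str = "sim"
    organelle: str = "nuclear"

    def per_gene_gc3(self) -> list[float]:
        if isinstance(self.gc3_target, (int, float)):
            return [float(self.gc3_target)] * self.n_genes
        if len(self.gc3_target) != self.n_genes:
            raise ValueError("gc3_target list must have one value per gene")
        return [float(v) for v in self.gc3_target]

    def per_gene_expression(self) -> list[float]:
        if self.expression is None:
            return [1.0] * self.n_genes
        if len(self.expression) != self.n_genes:
            raise ValueError("expression list must have one weight per gene")
        if any(g <= 0 for g in self.expression):
            raise ValueError("expression weights must be positive")
        return [float(g) for g in self.expression]


def simulate_trnaome(
    code: GeneticCode, coverage: str = "full", seed: int | None = None,
    genome_id: str = "sim", organelle: str = "nuclear",
) -> TRNAome:
    """A tRNAome that either decodes every sense codon ("full") or carries
    exactly one anticodon per amino acid ("sparse", mitochondrion-like)."""
    if coverage not in ("full", "sparse"):
        raise ValueError(f"coverage must be 'full' or 'sparse', got {coverage!r}")
    rng = np.random.default_rng(seed)
    rules = WobbleRules(mode="crick")
    copy_numbers: dict[str, int] = {}

    def anticodon(prefix: str, base34: str) -> str:
        # prefix = codon positions 1-2; anticodon is 5'->3'
        return base34 + COMPLEMENT[prefix[1]] + COMPLEMENT[prefix[0]]

    for fam in code.families().values():
        boxes: dict[str, set[str]] = {}
        for c in fam:
            boxes.setdefault(c[:2], set()).add(c[2])
        if coverage == "sparse":
            # one anticodon for the whole amino acid: largest box, most
            # versatile wobble base (ties broken toward U then G)
            prefix = max(sorted(boxes), key=lambda p: len(boxes[p]))
            thirds = boxes[prefix]
            best = max(
                "UGAC", key=lambda b: (len(rules.pairings[b] & thirds), b in "UG")
            )
            copy_numbers[anticodon(prefix, best)] = int(rng.integers(1, 3))
            continue
        for prefix, thirds in sorted(boxes.items()):
            chosen: list[str] = []
            remaining = set(thirds)
            for b in "UG":  # U34 reads A/G, G34 reads C/U: two cover any box
                readable = rules.pairings[b] & remaining
                if readable:
                    chosen.append(b)
                    remaining -= readable
            for t in sorted(remaining):  # leftovers get Watson-Crick anticodons
                chosen.append(COMPLEMENT[t])
            for b in chosen:
                copy_numbers[anticodon(prefix, b)] = int(rng.integers(1, 5))
    return TRNAome(genome_id=genome_id, organelle=organelle, copy_numbers=copy_numbers)


def _third_base_prob(gc3: float) -> dict[str, float]:
    return {"G": gc3 / 2, "C": gc3 / 2, "A": (1 - gc3) / 2, "U": (1 - gc3) / 2}


def simulate_genes(spec: SyntheticSpec, wi: WiVector | None = None) -> list[CodonCounts]:
    """Simulate per-gene codon counts under mutation bias and optional selection.

    With beta > 0 a WiVector is required; with beta = 0 codon choice within
    each family depends only on the mutational third-base weights.
    """
    if spec.n_genes < 1 or spec.gene_length < 1:
        raise ValueError("n_genes and gene_length must be positive")
    if spec.beta < 0:
        raise ValueError("beta must be >= 0")
    if spec.beta > 0 and wi is None:
        raise ValueError("selection (beta > 0) requires a wi vector")
    code = build_genetic_code(spec.code_id)
    families = [fam for fam in code.families().values() if len(fam) > 1]
    rng = np.random.default_rng(spec.seed)
    gc3s = spec.per_gene_gc3()
    expr = spec.per_gene_expression()

    genes: list[CodonCounts] = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        p3 = _third_base_prob(gc3s[i])
        # codons per family ~ multinomial over uniform family choice
        fam_counts = rng.multinomial(spec.gene_length, [1 / len(families)] * len(families))
        counts: dict[str, int] = {}
        for fam, n_fam in zip(families, fam_counts):
            if n_fam == 0:
                continue
            weights = np.array(
                [
                    p3[c[2]]
                    * (np.exp(spec.beta * expr[i] * wi.values[c]) if spec.beta > 0 else 1.0)
                    for c in fam
                ]
            )
            weights /= weights.sum()
            draws = rng.multinomial(n_fam, weights)
            for c, x in zip(fam, draws):
                if x:
                    counts[c] = counts.get(c, 0) + int(x)
        genes.append(
            CodonCounts(
                gene_id=f"g{i + 1:0{width}d}",
                genome_id=spec.genome_id,
                organelle=spec.organelle,
                counts=counts,
                n_codons=spec.gene_length,
                code_id=code.code_id,
            )
        )
    return genes


def counts_to_sequence(counts: CodonCounts, seed: int | None = None) -> str:
    """Expand codon counts into a concrete CDS (codon order shuffled)."""
    rng = np.random.default_rng(seed)
    codons = [c for codon, n in sorted(counts.counts.items()) for c in [codon] * n]
    rng.shuffle(codons)
    return "".join(codons).replace("U", "T")


#: documented seeds for the packaged scenarios
SCENARIO_SEEDS = {"neutral": 101, "selected": 202, "two_class": 303}


def scenario(name: str) -> tuple[list[SyntheticSpec], TRNAome]:
    """Packaged fixtures: 'neutral', 'selected' and 'two_class'."""
    if name not in SCENARIO_SEEDS:
        raise ValueError(f"unknown scenario {name!r}")
    seed = SCENARIO_SEEDS[name]
    code = build_genetic_code("standard")
    trnaome = simulate_trnaome(code, coverage="full", seed=seed, genome_id=f"{name}_trna")
    if name == "neutral":
        specs = [
            SyntheticSpec(
                n_genes=200, gene_length=400, gc3_target=0.5, beta=0.0,
                seed=seed, genome_id="neutral",
            )
        ]
    elif name == "selected":
        rng = np.random.default_rng(seed)
        expr = list(rng.lognormal(0.0, 1.0, 200))
        specs = [
            SyntheticSpec(
                n_genes=200, gene_length=400, gc3_target=0.5, beta=2.0,
                expression=expr, seed=seed, genome_id="selected",
            )
        ]
    else:  # two_class
        specs = [
            SyntheticSpec(
                n_genes=100, gene_length=400, gc3_target=0.25, beta=0.0,
                seed=seed, genome_id="low_gc3",
            ),
            SyntheticSpec(
                n_genes=100, gene_length=400, gc3_target=0.75, beta=0.0,
                seed=seed + 1, genome_id="high_gc3",
            ),
        ]
    return specs, trnaome


def scenario_wi(trnaome: TRNAome, code_id: str = "standard") -> WiVector:
    """Convenience: default-constraint wi vector for a scenario tRNAome."""
    return compute_wi(trnaome, default_s_vector(), build_genetic_code(code_id))
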