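"""Self-contained recomputations behind the desk-scale acceptance checks.

Shared by tests/test_acceptance.py and scripts/acceptance.py so both run the
exact same battery: analytic ENc/RSCU identities, S-test calibration and
power under the synthetic generators, and the neutral ENc-GC3 cloud fit.
"""

from __future__ import annotations

import numpy as np

from mitocub.codon_core import CodonCounts, build_genetic_code
from mitocub.cub_metrics import enc, enc_from_class_means, neutral_fit, rscu
from mitocub.synthetic_data import SyntheticSpec, simulate_genes, simulate_trnaome
from mitocub.trna_selection import compute_wi, default_s_vector, permutation_s_test


def make_counts(counts: dict, code_id="standard") -> CodonCounts:
    return CodonCounts(
        gene_id="acc",
        genome_id="acc",
        organelle="mito",
        counts=dict(counts),
        n_codons=sum(counts.values()),
        code_id=code_id,
    )


def enc_one_codon_per_family(copies: int = 10) -> float:
    """ENc for a gene using exactly one codon per standard-code family."""
    code = build_genetic_code("standard")
    counts = {fam[0]: copies for fam in code.families().values()}
    return enc(make_counts(counts), code).enc


def enc_equal_usage_limit() -> float:
    """ENc with every class mean homozygosity at its uniform value 1/k."""
    code = build_genetic_code("standard")
    return enc_from_class_means({2: 1 / 2, 3: 1 / 3, 4: 1 / 4, 6: 1 / 6}, code)


def rscu_sole_fourfold() -> float:
    """RSCU of ACC when threonine occurs once, encoded by ACC."""
    code = build_genetic_code("standard")
    return rscu(make_counts({"ACC": 1}), code).values["ACC"]


def rscu_one_of_three() -> float:
    """RSCU of CCG with proline used three times, once as CCG."""
    code = build_genetic_code("standard")
    return rscu(make_counts({"CCG": 1, "CCU": 2}), code).values["CCG"]


def rscu_uniform_family() -> float:
    """Common RSCU of equally used alanine codons."""
    code = build_genetic_code("standard")
    counts = {"GCU": 5, "GCC": 5, "GCA": 5, "GCG": 5}
    vals = {c: rscu(make_counts(counts), code).values[c] for c in counts}
    (common,) = set(vals.values())
    return common


def stest_battery(
    beta: float,
    n_genomes: int,
    seed: int,
    n_genes: int = 30,
    gene_length: int = 300,
    n_perm: int = 100,
) -> dict:
    """Simulate genomes, run the permutation S-test on each, summarize.

    Returns the significant fraction and the per-genome S values.  The wi
    vector is derived from a full-coverage simulated tRNAome; expression
    weights are lognormal when selection is on (the selection signal needs
    between-gene variation in selection strength to be detectable).
    """
    code = build_genetic_code("standard")
    trnaome = simulate_trnaome(code, "full", seed=101)
    wi = compute_wi(trnaome, default_s_vector(), code)
    n_sig = 0
    s_values = []
    for i in range(n_genomes):
        rng = np.random.default_rng(seed + i)
        expr = list(rng.lognormal(0.0, 1.0, n_genes)) if beta > 0 else None
        spec = SyntheticSpec(
            n_genes=n_genes,
            gene_length=gene_length,
            gc3_target=0.5,
            beta=beta,
            expression=expr,
            seed=seed + i,
            genome_id=f"sim{i}",
        )
        genes = simulate_genes(spec, wi if beta > 0 else None)
        points = [enc(g, code) for g in genes]
        result = permutation_s_test(
            genes, points, wi, n_perm=n_perm, seed=seed + 10_000 + i
        )
        n_sig += result.significant
        s_values.append(result.s_value)
    return {
        "beta": beta,
        "n_genomes": n_genomes,
        "significant_fraction": n_sig / n_genomes,
        "median_s": float(np.median(s_values)),
        "s_values": s_values,
    }


def neutral_cloud_fit(
    seed: int, n_genes: int = 150, gene_length: int = 1000
) -> float:
    """R^2 of a neutral (GC3, ENc) cloud against the expectation curve."""
    code = build_genetic_code("standard")
    rng = np.random.default_rng(seed)
    gc3s = list(rng.uniform(0.15, 0.85, n_genes))
    spec = SyntheticSpec(
        n_genes=n_genes, gene_length=gene_length, gc3_target=gc3s, seed=seed
    )
    points = [enc(g, code) for g in simulate_genes(spec)]
    return neutral_fit(points).r2
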