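"""tRNA adaptation (wi, tAI) and the permutation test for translational selection.

For each sense codon c the raw adaptiveness is
``W_c = sum over pairing tRNAs of (1 - s_pairing) * tGCN``,
normalized to ``wi = W / max(W)``; codons with W = 0 take the geometric
mean of the nonzero wi values.  A gene's tAI is the count-weighted
geometric mean of its codons' wi.  The S statistic correlates per-gene tAI
with the relative ENc deviation from the neutral curve; its null is formed
by permuting the wi multiset over codons and recomputing everything.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from mitocub.codon_core import COMPLEMENT, RNA_BASES, CodonCounts, GeneticCode
from mitocub.cub_metrics import EncPoint


@dataclass
class TRNAome:
    """Anticodon gene copy numbers (tGCN) for one genome."""

    genome_id: str
    organelle: str
    copy_numbers: dict[str, int]  # anticodon (RNA 5'->3') -> copies

    def __post_init__(self) -> None:
        clean = {}
        for ac, n in self.copy_numbers.items():
            ac = ac.upper().replace("T", "U")
            if len(ac) != 3:
                raise ValueError(f"anticodon {ac!r} is not a 3-mer")
            clean[ac] = clean.get(ac, 0) + int(n)
        self.copy_numbers = clean
        if sum(self.copy_numbers.values()) < 1:
            raise ValueError(f"{self.genome_id}: empty tRNAome")


@dataclass(frozen=True)
class SVector:
    """Selective constraints per anticodon(34):codon(3) pairing class.

    Keys are ``"X:Y"`` with X the anticodon wobble base (``I`` = inosine)
    and Y the codon third base; values lie in [0, 1], 0 meaning a fully
    efficient pairing.  Pairings absent from the map do not occur.
    """

    constraints: tuple  # tuple of (pairing, s) pairs; kept hashable
    assume_inosine: bool = True

    def __post_init__(self) -> None:
        for pairing, s in self.constraints:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"constraint {pairing} = {s} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(self.constraints)

    def with_constraint(self, pairing: str, s: float) -> "SVector":
        d = self.as_dict()
        if pairing not in d:
            raise KeyError(f"unknown pairing class {pairing!r}")
        d[pairing] = s
        return replace(self, constraints=tuple(sorted(d.items())))


def default_s_vector(assume_inosine: bool = True) -> SVector:
    """Load the packaged default constraints (reference tAI values)."""
    text = (
        importlib.resources.files("mitocub.data")
        .joinpath("s_vector_defaults.tsv")
        .read_text(encoding="utf-8")
    )
    constraints = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pairing, s = line.split("\t")
        constraints[pairing] = float(s)
    return SVector(constraints=tuple(sorted(constraints.items())), assume_inosine=assume_inosine)


@dataclass
class WiVector:
    values: dict[str, float]  # sense codon -> wi in (0, 1]
    zero_replaced: list[str] = field(default_factory=list)
    code_id: str = "standard"


@dataclass
class TaiResult:
    gene_id: str
    tai: float


@dataclass
class STestResult:
    genome_id: str
    s_value: float
    correlation_type: str
    n_perm: int
    perm_values: list[float]
    empirical_p: float
    significant: bool
    seed: int | None


def compute_wi(trnaome: TRNAome, s: SVector | None = None, code: GeneticCode | None = None) -> WiVector:
    """Per-codon relative adaptiveness from tRNA gene copy numbers."""
    if code is None:
        raise ValueError("a genetic code is required")
    s = s or default_s_vector()
    constraints = s.as_dict()
    w: dict[str, float] = {c: 0.0 for c in code.sense_codons}
    for anticodon, copies in trnaome.copy_numbers.items():
        if any(b not in RNA_BASES for b in anticodon):
            continue  # unknown anticodon, cannot pair
        base34 = anticodon[0]
        wobble_bases = [base34]
        if base34 == "A" and s.assume_inosine:
            wobble_bases = ["I"]
        prefix = COMPLEMENT[anticodon[2]] + COMPLEMENT[anticodon[1]]
        for b34 in wobble_bases:
            for third in RNA_BASES:
                pairing = f"{b34}:{third}"
                if pairing not in constraints:
                    continue
                codon = prefix + third
                if codon in w:
                    w[codon] += (1.0 - constraints[pairing]) * copies

    wmax = max(w.values())
    if wmax <= 0:
        raise ValueError(f"{trnaome.genome_id}: no codon is decodable by this tRNAome")
    wi = {c: v / wmax for c, v in w.items()}
    nonzero = [v for v in wi.values() if v > 0]
    geo = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    zero_replaced = sorted(c for c, v in wi.items() if v == 0)
    for c in zero_replaced:
        wi[c] = geo
    return WiVector(values=wi, zero_replaced=zero_replaced, code_id=code.code_id)


def tai(counts: CodonCounts, wi: WiVector) -> TaiResult:
    """Count-weighted geometric mean of wi over a gene's sense codons."""
    log_sum = 0.0
    n = 0
    for codon, x in counts.counts.items():
        v = wi.values.get(codon)
        if v is None or x == 0:
            continue
        log_sum += x * math.log(v)
        n += x
    if n == 0:
        raise ValueError(f"{counts.gene_id}: no codons with defined wi")
    return TaiResult(gene_id=counts.gene_id, tai=math.exp(log_sum / n))


def s_statistic(points: list[tuple[float, float]], method: str = "pearson") -> float:
    """Correlation between per-gene tAI and per-gene ENc deviation."""
    if len(points) < 3:
        raise ValueError(f"S statistic needs >=3 gene points, got {len(points)}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant tAI across genes: S undefined")
    if np.ptp(y) == 0:
        raise ValueError("constant ENc deviation across genes: S undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation type {method!r}")


def _tai_matrix(gene_counts: list[CodonCounts], codons: list[str]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(codons)}
    C = np.zeros((len(gene_counts), len(codons)))
    for i, g in enumerate(gene_counts):
        for codon, x in g.counts.items():
            j = idx.get(codon)
            if j is not None:
                C[i, j] = x
    return C


def permutation_s_test(
    gene_counts: list[CodonCounts],
    encpoints: list[EncPoint],
    wi: WiVector,
    n_perm: int = 100,
    seed: int | None = None,
    method: str = "pearson",
) -> STestResult:
    """S statistic with a permutation null that shuffles wi over codons.

    Significance follows the top-5% rule: the observed S must reach the
    95th percentile of the permuted values.  The reported empirical p uses
    the add-one correction, (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(gene_counts) != len(encpoints):
        raise ValueError("gene_counts and encpoints must align")
    order = {p.gene_id: p for p in encpoints}
    devs = np.array([order[g.gene_id].deviation for g in gene_counts])

    codons = sorted(wi.values)
    C = _tai_matrix(gene_counts, codons)
    row_tot = C.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError("gene with no usable codons in S-test")
    logw = np.log(np.array([wi.values[c] for c in codons]))

    def s_of(logw_vec: np.ndarray) -> float:
        tais = np.exp(C @ logw_vec / row_tot)
        return s_statistic(list(zip(tais, devs)), method=method)

    observed = s_of(logw)
    rng = np.random.default_rng(seed)
    perm_values = [s_of(rng.permutation(logw)) for _ in range(n_perm)]
    emp_p = (1 + sum(1 for v in perm_values if v >= observed)) / (n_perm + 1)
    threshold = float(np.quantile(perm_values, 0.95))
    return STestResult(
        genome_id=gene_counts[0].genome_id,
        s_value=observed,
        correlation_type=method,
        n_perm=n_perm,
        perm_values=perm_values,
        empirical_p=emp_p,
        significant=observed >= threshold,
        seed=seed,
    )


def optimize_s_vector(
    gene_counts: list[CodonCounts],
    encpoints: list[EncPoint],
    trnaome: TRNAome,
    code: GeneticCode,
    bounds: tuple[float, float] = (0.0, 1.0),
    objective=None,
    seed: int | None = None,
    n_iter: int = 200,
    step: float = 0.15,
    method: str = "pearson",
) -> tuple[SVector, list[tuple[int, str, float, float]]]:
    """Hill-climb the wobble constraints to maximize an objective.

    Only non-Watson-Crick pairing classes are perturbed.  The default
    objective is the S correlation itself, recomputed from scratch for each
    candidate vector.  Returns the best vector and an acceptance trace of
    (iteration, pairing, value, objective) tuples; the objective is
    non-decreasing along the trace.
    """
    order = {p.gene_id: p for p in encpoints}
    devs = [order[g.gene_id].deviation for g in gene_counts]

    def default_objective(s_vec: SVector) -> float:
        wi = compute_wi(trnaome, s_vec, code)
        tais = [tai(g, wi).tai for g in gene_counts]
        return s_statistic(list(zip(tais, devs)), method=method)

    objective = objective or default_objective
    current = default_s_vector()
    wobble_keys = sorted(k for k, v in current.as_dict().items() if v > 0)
    best_obj = objective(current)
    if math.isnan(best_obj):
        raise ValueError("objective undefined at the initial s-vector")
    trace: list[tuple[int, str, float, float]] = [(0, "init", math.nan, best_obj)]
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    for it in range(1, n_iter + 1):
        key = wobble_keys[int(rng.integers(len(wobble_keys)))]
        proposal = float(np.clip(current.as_dict()[key] + rng.normal(0, step), lo, hi))
        candidate = current.with_constraint(key, proposal)
        obj = objective(candidate)
        if obj >= best_obj:
            current, best_obj = candidate, obj
            trace.append((it, key, proposal, obj))
    return current, trace
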