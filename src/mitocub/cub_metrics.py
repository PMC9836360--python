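"""Gene-level codon usage statistics: RSCU, GC/GC3, ENc and the neutral curve.

ENc follows Wright's estimator: per-family homozygosity
``F = (n * sum(p^2) - 1) / (n - 1)`` averaged within degeneracy classes,
then ``ENc = n_single + sum_k m_k / Fbar_k``.  The neutral expectation is
``g(s) = 2 + s + 29 / (s^2 + (1 - s)^2)`` with s the (synonymous) GC3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from mitocub.codon_core import (
    CodonCounts,
    CodonUsageError,
    FamilyPolicy,
    GeneticCode,
    count_codons,
)


@dataclass
class RSCUVector:
    """Per-codon relative synonymous codon usage for one gene or genome.

    ``values[c]`` is observed count / (family total / family size); ``None``
    marks codons whose family has no observation.
    """

    owner_id: str
    values: dict[str, float | None]
    family_policy: FamilyPolicy
    code_id: str


@dataclass
class EncPoint:
    gene_id: str
    enc: float
    gc3: float  # synonymous-sites GC3 (GC3s), used for the neutral curve
    enc_expected: float
    deviation: float
    gc: float = math.nan
    gc3_all: float = math.nan  # plain GC3 over all codons
    enc_raw: float = math.nan  # uncapped diagnostic value
    class_fs: dict[int, float] = field(default_factory=dict)
    imputed_classes: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class NeutralFit:
    """Fit of observed ENc values to the neutral ENc-GC3 curve.

    r2 = 1 - SS_res / SS_tot where residuals are taken against the curve
    itself, not a refitted regression; r2 may be negative.
    """

    r2: float
    n_genes: int
    residuals: dict[str, float]  # gene_id -> expected - observed
    reason: str | None = None


def rscu(
    counts: CodonCounts,
    code: GeneticCode,
    policy: FamilyPolicy | None = None,
) -> RSCUVector:
    """Relative synonymous codon usage under the given family policy.

    For codon j in a family of size k with family total N,
    RSCU_j = X_j / (N / k).  Families with N = 0 yield None for all their
    codons; stop codons (and, under the default policy, single-codon
    families) are excluded from the vector entirely.
    """
    policy = policy or FamilyPolicy()
    values: dict[str, float | None] = {}
    for fam in code.families(policy).values():
        k = len(fam)
        if k == 1 and policy.exclude_nondegenerate:
            continue
        total = sum(counts.counts.get(c, 0) for c in fam)
        for c in fam:
            values[c] = None if total == 0 else counts.counts.get(c, 0) * k / total
    return RSCUVector(
        owner_id=counts.gene_id,
        values=values,
        family_policy=policy,
        code_id=code.code_id,
    )


@dataclass(frozen=True)
class GCStats:
    gc: float
    gc3: float  # GC3s: third positions of degenerate-family codons only
    gc3_all: float


def gc_content(counts: CodonCounts | str, code: GeneticCode) -> GCStats:
    """GC fraction over all positions, plus GC3 at third codon positions.

    ``gc3`` follows the synonymous-sites convention (codons of single-codon
    families excluded); ``gc3_all`` uses every counted codon.  Accepts a raw
    coding sequence, which is codon-counted first.
    """
    if isinstance(counts, str):
        counts = count_codons(counts, code)
    degenerate = {
        c for fam in code.families().values() if len(fam) > 1 for c in fam
    }
    gc_positions = total_positions = 0
    gc3_syn = n_syn = gc3_any = n_any = 0
    for codon, n in counts.counts.items():
        gc_positions += n * sum(b in "GC" for b in codon)
        total_positions += 3 * n
        third_is_gc = codon[2] in "GC"
        gc3_any += n * third_is_gc
        n_any += n
        if codon in degenerate:
            gc3_syn += n * third_is_gc
            n_syn += n
    return GCStats(
        gc=gc_positions / total_positions if total_positions else math.nan,
        gc3=gc3_syn / n_syn if n_syn else math.nan,
        gc3_all=gc3_any / n_any if n_any else math.nan,
    )


def _family_homozygosity(counts: CodonCounts, fam: tuple[str, ...]) -> float | None:
    """Wright's F-hat for one family; None when n < 2 or F <= 0."""
    obs = [counts.counts.get(c, 0) for c in fam]
    n = sum(obs)
    if n < 2:
        return None
    f = (n * sum((x / n) ** 2 for x in obs) - 1) / (n - 1)
    return f if f > 0 else None


def enc_from_class_means(
    class_means: dict[int, float], code: GeneticCode
) -> float:
    """ENc from fixed per-class mean homozygosities (analytic path).

    With every Fbar_k at its uniform value 1/k this returns the code's
    theoretical maximum (61 for the standard code).
    """
    classes = code.degeneracy_classes
    total = float(len(classes.get(1, ())))
    for k, fams in classes.items():
        if k == 1:
            continue
        fbar = class_means.get(k)
        if fbar is None or fbar <= 0:
            raise ValueError(f"missing or non-positive mean homozygosity for class {k}")
        total += len(fams) / fbar
    return total


def enc(counts: CodonCounts, code: GeneticCode) -> EncPoint:
    """Wright's effective number of codons, with GC3 and the neutral curve.

    Classes with no valid family homozygosity borrow the mean of adjacent
    classes (e.g. threefold <- average of the twofold and fourfold means);
    genes needing more than two such imputations are flagged low_confidence.
    The reported ENc is capped to [1, enc_max]; the raw value is kept in
    ``enc_raw``.
    """
    classes = code.degeneracy_classes
    n_single = len(classes.get(1, ()))
    sizes = sorted(k for k in classes if k > 1)

    class_fs: dict[int, float] = {}
    for k in sizes:
        fs = [f for fam in classes[k] if (f := _family_homozygosity(counts, fam)) is not None]
        if fs:
            class_fs[k] = sum(fs) / len(fs)

    if not class_fs:
        raise CodonUsageError(
            f"{counts.gene_id}: no degenerate family with enough observations for ENc"
        )

    imputed: list[int] = []
    flags: list[str] = []
    filled = dict(class_fs)
    for i, k in enumerate(sizes):
        if k in filled:
            continue
        neighbours = [
            filled[sizes[j]]
            for j in (i - 1, i + 1)
            if 0 <= j < len(sizes) and sizes[j] in class_fs
        ]
        if not neighbours:  # fall back to any observed class
            neighbours = list(class_fs.values())
        filled[k] = sum(neighbours) / len(neighbours)
        imputed.append(k)
    if len(imputed) > 2:
        flags.append("low_confidence")

    enc_raw = n_single + sum(len(classes[k]) / filled[k] for k in sizes)
    enc_val = min(max(enc_raw, 1.0), float(code.enc_max))

    gc = gc_content(counts, code)
    expected = expected_enc(gc.gc3) if not math.isnan(gc.gc3) else math.nan
    dev = (expected - enc_val) / expected if expected and not math.isnan(expected) else math.nan
    return EncPoint(
        gene_id=counts.gene_id,
        enc=enc_val,
        gc3=gc.gc3,
        enc_expected=expected,
        deviation=dev,
        gc=gc.gc,
        gc3_all=gc.gc3_all,
        enc_raw=enc_raw,
        class_fs=filled,
        imputed_classes=imputed,
        flags=flags,
    )


def expected_enc(gc3: float) -> float:
    """Neutral-expectation curve g(s) = 2 + s + 29 / (s^2 + (1-s)^2)."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3 must lie in [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3 ** 2 + (1.0 - gc3) ** 2)


def neutral_fit(points: list[EncPoint]) -> NeutralFit:
    """R-squared of observed ENc against the neutral curve at each gene's GC3."""
    valid = [
        p
        for p in points
        if not (math.isnan(p.enc) or math.isnan(p.gc3) or math.isnan(p.enc_expected))
    ]
    if len(valid) < 3:
        raise ValueError(f"neutral fit needs >=3 valid points, got {len(valid)}")
    mean_enc = sum(p.enc for p in valid) / len(valid)
    ss_tot = sum((p.enc - mean_enc) ** 2 for p in valid)
    residuals = {p.gene_id: p.enc_expected - p.enc for p in valid}
    if ss_tot == 0:
        return NeutralFit(
            r2=math.nan,
            n_genes=len(valid),
            residuals=residuals,
            reason="all observed ENc values identical (SS_tot = 0)",
        )
    ss_res = sum((p.enc - p.enc_expected) ** 2 for p in valid)
    return NeutralFit(r2=1.0 - ss_res / ss_tot, n_genes=len(valid), residuals=residuals)


def deviation(point: EncPoint) -> float:
    """Relative deviation from the neutral expectation, (expected - enc) / expected."""
    if math.isnan(point.enc):
        raise ValueError(f"{point.gene_id}: missing ENc")
    if not point.enc_expected > 0:
        raise ValueError(f"{point.gene_id}: non-positive expected ENc")
    return (point.enc_expected - point.enc) / point.enc_expected
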