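"""Decoding capacity of a tRNAome under explicit wobble rules.

Orientation convention, pinned because it is the classic silent-bug source:
anticodons are written 5'->3'; their first base (position 34) pairs codon
position 3, and positions 35-36 pair codon positions 2-1 by Watson-Crick
rules (antiparallel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitocub.codon_core import COMPLEMENT, RNA_BASES, GeneticCode
from mitocub.trna_selection import TRNAome

#: wobble-position pairings per mode: anticodon base 34 -> readable codon-3 bases
_STRICT = {"A": {"U"}, "C": {"G"}, "G": {"C"}, "U": {"A"}}
_CRICK = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}
_INOSINE_34 = {"U", "C", "A"}  # A34 deaminated to inosine


@dataclass(frozen=True)
class WobbleRules:
    mode: str = "crick"
    assume_inosine: bool = True  # only consulted by the extended mode
    pairings: dict = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "crick", "extended"):
            raise ValueError(f"unknown wobble mode {self.mode!r}")
        base = {k: set(v) for k, v in (_STRICT if self.mode == "strict" else _CRICK).items()}
        if self.mode == "extended" and self.assume_inosine:
            base["A"] = base["A"] | _INOSINE_34
        object.__setattr__(self, "pairings", base)


@dataclass
class DecodabilityReport:
    genome_id: str
    decodable: dict[str, bool]  # sense codon -> flag
    undecodable_set: list[str]
    rules_used: WobbleRules
    supporting: dict[str, list[str]] = field(default_factory=dict)  # codon -> anticodons


@dataclass
class VersatilityVerdict:
    family_id: str
    observed_wobble_base: str
    versatility_maximizing: bool
    note: str = ""


def anticodon_to_codons(anticodon: str, rules: WobbleRules) -> set[str]:
    """Codons readable by an anticodon under the given wobble rules."""
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or any(b not in RNA_BASES for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    prefix = COMPLEMENT[ac[2]] + COMPLEMENT[ac[1]]  # codon positions 1-2
    return {prefix + third for third in rules.pairings[ac[0]]}


def decodability(
    trnaome: TRNAome, code: GeneticCode, rules: WobbleRules | None = None
) -> DecodabilityReport:
    """Which sense codons the tRNAome can read; the complement is undecodable."""
    rules = rules or WobbleRules()
    supporting: dict[str, list[str]] = {}
    for anticodon, n in sorted(trnaome.copy_numbers.items()):
        if n < 1 or any(b not in RNA_BASES for b in anticodon):
            continue
        for codon in anticodon_to_codons(anticodon, rules):
            supporting.setdefault(codon, []).append(anticodon)
    decodable = {c: c in supporting for c in code.sense_codons}
    return DecodabilityReport(
        genome_id=trnaome.genome_id,
        decodable=decodable,
        undecodable_set=sorted(c for c, ok in decodable.items() if not ok),
        rules_used=rules,
        supporting={c: supporting[c] for c in sorted(supporting) if c in decodable},
    )


def _box_coverage(base34: str, third_bases: set[str], rules: WobbleRules) -> int:
    return len(rules.pairings[base34] & third_bases)


def versatility_check(
    trnaome: TRNAome, code: GeneticCode, rules: WobbleRules | None = None
) -> list[VersatilityVerdict]:
    """Does each family's wobble base maximize the codons it can read?

    Each anticodon is assigned to its Watson-Crick codon's synonymous
    family and judged within its codon box (family codons sharing the
    anticodon-determined first two bases): the verdict is positive when the
    observed base 34 reads at least as many box codons as any alternative
    base would under the same rules.  Anticodons whose WC codon is a stop
    are flagged, not fatal.
    """
    rules = rules or WobbleRules()
    families = code.families()  # unsplit, keyed by amino acid
    per_family: dict[str, list[tuple[str, bool, str]]] = {}
    flagged: list[VersatilityVerdict] = []

    for anticodon in sorted(trnaome.copy_numbers):
        if any(b not in RNA_BASES for b in anticodon):
            flagged.append(
                VersatilityVerdict(
                    family_id="?",
                    observed_wobble_base="?",
                    versatility_maximizing=False,
                    note=f"anticodon {anticodon} unknown; skipped",
                )
            )
            continue
        wc_codon = COMPLEMENT[anticodon[2]] + COMPLEMENT[anticodon[1]] + COMPLEMENT[anticodon[0]]
        aa = code.codon_to_aa[wc_codon]
        if aa == "*":
            flagged.append(
                VersatilityVerdict(
                    family_id="*",
                    observed_wobble_base=anticodon[0],
                    versatility_maximizing=False,
                    note=f"anticodon {anticodon} Watson-Crick pairs a stop codon",
                )
            )
            continue
        fam = families[aa]
        box_thirds = {c[2] for c in fam if c[:2] == wc_codon[:2]}
        observed = _box_coverage(anticodon[0], box_thirds, rules)
        best = max(_box_coverage(b, box_thirds, rules) for b in RNA_BASES)
        per_family.setdefault(aa, []).append(
            (anticodon, observed >= best, f"{anticodon} reads {observed}/{len(box_thirds)} box codons (best {best})")
        )

    verdicts: list[VersatilityVerdict] = []
    for aa, entries in sorted(per_family.items()):
        maximizing = all(ok for _, ok, _ in entries)
        notes = "; ".join(note for _, _, note in entries)
        verdicts.append(
            VersatilityVerdict(
                family_id=aa,
                observed_wobble_base=",".join(sorted({a[0] for a, _, _ in entries})),
                versatility_maximizing=maximizing,
                note=notes,
            )
        )
    return verdicts + flagged
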