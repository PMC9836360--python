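"""End-to-end orchestration: config validation and the per-run report bundle.

A run is described by one declarative YAML config; all randomness hangs off
a single seed and every output directory carries a manifest with the config
hash, so identical config + inputs give identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from mitocub import codon_core, cub_metrics, multivariate, sequence_io, trna_selection, wobble

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_CONFIG_ERROR, EXIT_DATA_ERROR = 0, 2, 3


@dataclass
class GenomeEntry:
    id: str
    organelle: str  # mito | nuclear
    cds_fasta: str | None = None
    genbank: str | None = None
    trna_tsv: str | None = None


@dataclass
class RunConfig:
    genomes: list[GenomeEntry]
    codes: dict = field(default_factory=lambda: {"mito": "mold_mito", "nuclear": "standard"})
    split_sixfold: bool = True
    exclude_nondegenerate: bool = True
    distance: str = "euclidean"
    linkage: str = "average"
    wobble_mode: str = "crick"
    n_perm: int = 100
    seed: int = 42
    correlation: str = "pearson"
    out_dir: str = "mitocub_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genomes = [GenomeEntry(**g) for g in raw.pop("genomes", [])]
        return cls(genomes=genomes, **raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[dict]:
    """Return a list of problems; empty iff the config is runnable.

    Each problem is {"level": "error"|"warning", "field": ..., "reason": ...}.
    """
    problems: list[dict] = []

    def err(fieldname, reason):
        problems.append({"level": "error", "field": fieldname, "reason": reason})

    def warn(fieldname, reason):
        problems.append({"level": "warning", "field": fieldname, "reason": reason})

    ids = [g.id for g in config.genomes]
    if not ids:
        err("genomes", "no genomes configured")
    if len(set(ids)) != len(ids):
        err("genomes", "duplicate genome ids")
    for g in config.genomes:
        if g.organelle not in ("mito", "nuclear"):
            err(f"genomes[{g.id}].organelle", f"unknown organelle {g.organelle!r}")
        if not g.cds_fasta and not g.genbank:
            err(f"genomes[{g.id}]", "needs either cds_fasta or genbank input")
        if g.cds_fasta and not g.trna_tsv and not g.genbank:
            err(f"genomes[{g.id}].trna_tsv", "S-test requires a tRNA source (trna_tsv or genbank)")
        code_id = config.codes.get(g.organelle)
        if g.organelle == "mito" and code_id == "standard":
            warn(f"genomes[{g.id}]", "mitochondrial genome analysed under the standard code")
    if config.n_perm < 1:
        err("n_perm", "n_perm must be >= 1")
    if config.correlation not in ("pearson", "spearman"):
        err("correlation", f"unknown correlation {config.correlation!r}")
    if config.wobble_mode not in ("strict", "crick", "extended"):
        err("wobble_mode", f"unknown wobble mode {config.wobble_mode!r}")
    return problems


class StageError(RuntimeError):
    def __init__(self, stage: str, genome: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for genome {genome!r}: {cause}")
        self.stage, self.genome = stage, genome


def _trnaome_from_rows(rows, genome_id, organelle) -> trna_selection.TRNAome:
    copies: dict[str, int] = {}
    for r in rows:
        if set(r.anticodon) - set("ACGU"):
            continue  # unknown anticodon, unusable for pairing
        copies[r.anticodon] = copies.get(r.anticodon, 0) + r.copy_number
    return trna_selection.TRNAome(genome_id=genome_id, organelle=organelle, copy_numbers=copies)


def run_report(config: RunConfig, progress: bool = True) -> dict:
    """Execute the full analysis battery and write the report bundle.

    Emits per-gene RSCU/ENc tables, genome-level RSCU, CA outputs, a
    dendrogram, wi/tAI tables, S-test results, decodability reports and a
    manifest.  Returns the manifest dict.
    """
    problems = [p for p in validate_config(config) if p["level"] == "error"]
    if problems:
        raise ValueError("invalid config: " + "; ".join(p["reason"] for p in problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    policy = codon_core.FamilyPolicy(
        split_sixfold=config.split_sixfold,
        exclude_nondegenerate=config.exclude_nondegenerate,
    )
    rules = wobble.WobbleRules(mode=config.wobble_mode)
    s_vec = trna_selection.default_s_vector()

    gene_vectors: list[cub_metrics.RSCUVector] = []
    genome_vectors: list[cub_metrics.RSCUVector] = []
    enc_rows: list[dict] = []
    stest_results: list[dict] = []
    decod_rows: list[dict] = []
    summaries: list[dict] = []

    for g in config.genomes:
        t0 = time.monotonic()
        code = codon_core.build_genetic_code(config.codes.get(g.organelle, "standard"))
        stage = "read_input"
        try:
            trna_rows = None
            if g.genbank:
                records, trna_rows, summary = sequence_io.extract_from_genbank(
                    g.genbank, genome_id=g.id, organelle=g.organelle
                )
                summaries.append(summary)
            else:
                records = sequence_io.read_cds_fasta(g.cds_fasta, g.id, g.organelle)
            if g.trna_tsv:
                trna_rows = sequence_io.read_trna_tsv(g.trna_tsv)

            stage = "count_codons"
            gene_counts = []
            for rec in records:
                if rec.flags:
                    logger.warning("skipping flagged gene %s (%s)", rec.gene_id, rec.flags)
                    continue
                gene_counts.append(
                    codon_core.count_codons(rec.sequence, code, rec.gene_id, g.id, g.organelle)
                )
            if not gene_counts:
                raise ValueError("no usable CDS")

            stage = "rscu"
            for gc in gene_counts:
                v = cub_metrics.rscu(gc, code, policy)
                v.owner_id = f"{g.id}:{gc.gene_id}"
                gene_vectors.append(v)
            pooled = codon_core.pool_counts(gene_counts, gene_id=g.id)
            genome_vectors.append(cub_metrics.rscu(pooled, code, policy))

            stage = "enc"
            points = []
            for gc in gene_counts:
                try:
                    p = cub_metrics.enc(gc, code)
                except codon_core.CodonUsageError as exc:
                    logger.warning("%s", exc)
                    continue
                points.append(p)
                enc_rows.append(
                    {
                        "genome_id": g.id,
                        "gene_id": p.gene_id,
                        "enc": p.enc,
                        "gc3": p.gc3,
                        "enc_expected": p.enc_expected,
                        "deviation": p.deviation,
                        "flags": ";".join(p.flags),
                    }
                )

            if trna_rows:
                stage = "trna_selection"
                trnaome = _trnaome_from_rows(trna_rows, g.id, g.organelle)
                wi = trna_selection.compute_wi(trnaome, s_vec, code)
                usable = [c for c, p in zip(gene_counts, points) if p is not None]
                res = trna_selection.permutation_s_test(
                    usable, points, wi,
                    n_perm=config.n_perm, seed=config.seed, method=config.correlation,
                )
                stest_results.append(
                    {
                        "genome_id": res.genome_id,
                        "organelle": g.organelle,
                        "s_value": res.s_value,
                        "empirical_p": res.empirical_p,
                        "significant": res.significant,
                        "n_perm": res.n_perm,
                        "correlation": res.correlation_type,
                    }
                )
                stage = "decodability"
                report = wobble.decodability(trnaome, code, rules)
                for codon, ok in sorted(report.decodable.items()):
                    decod_rows.append(
                        {
                            "genome_id": g.id,
                            "codon": codon,
                            "decodable": ok,
                            "anticodons": ";".join(report.supporting.get(codon, [])),
                        }
                    )
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(stage, g.id, exc) from exc
        if progress:
            logger.info("genome %s done in %.2fs", g.id, time.monotonic() - t0)

    # cross-genome stages
    try:
        stage = "correspondence_analysis"
        ca_files = {}
        if len(gene_vectors) >= 2:
            matrix = multivariate.build_rscu_matrix(gene_vectors)
            ca = multivariate.correspondence_analysis(matrix)
            ca.row_coords.to_csv(out / "ca_row_coords.tsv", sep="\t")
            ca.col_coords.to_csv(out / "ca_col_coords.tsv", sep="\t")
            ca.col_contrib.to_csv(out / "ca_col_contrib.tsv", sep="\t")
            eig_rows = [
                {"dim": i + 1, "eigenvalue": ev, "pct_inertia": pct}
                for i, (ev, pct) in enumerate(zip(ca.eigenvalues, ca.pct_inertia))
            ]
            sequence_io.write_table(eig_rows, out / "ca_eigenvalues.tsv")
            ca_files = {"eigenvalues": "ca_eigenvalues.tsv"}
        stage = "clustering"
        newick_file = None
        if len(genome_vectors) >= 2:
            dendro = multivariate.hierarchical_cluster(
                genome_vectors, distance=config.distance, linkage=config.linkage
            )
            (out / "dendrogram.nwk").write_text(dendro.newick + "\n")
            newick_file = "dendrogram.nwk"
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "<all>", exc) from exc

    sequence_io.write_table(enc_rows, out / "enc_gc3.tsv")
    rscu_rows = [
        {"owner_id": v.owner_id, **{c: (val if val is not None else "NA") for c, val in sorted(v.values.items())}}
        for v in gene_vectors
    ]
    sequence_io.write_table(rscu_rows, out / "rscu_genes.tsv")
    genome_rscu_rows = [
        {"owner_id": v.owner_id, **{c: (val if val is not None else "NA") for c, val in sorted(v.values.items())}}
        for v in genome_vectors
    ]
    sequence_io.write_table(genome_rscu_rows, out / "rscu_genomes.tsv")
    if stest_results:
        sequence_io.write_table(stest_results, out / "stest.tsv")
    if decod_rows:
        sequence_io.write_table(decod_rows, out / "decodability.tsv")
    if summaries:
        sequence_io.write_table(summaries, out / "genome_summaries.tsv")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genomes": len(config.genomes),
        "n_genes": len(gene_vectors),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "ca": ca_files,
        "dendrogram": newick_file,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
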