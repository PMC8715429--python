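"""End-to-end workflows wiring the analysis modules together.

Two workflows mirror the two halves of the method: ``run_insilico`` takes a
directory of annotated genomes and produces the discrimination reports
(regions, entropy, identifiability, OTU metrics, classification accuracy);
``run_read_pipeline`` drives the read-processing stages from filtered pairs
through cleanup, abundance and copy-number calling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import (
    conservation,
    genome_io,
    identifiability,
    otu_metrics,
    pipeline_core,
    primer_regions,
    taxon_classifier,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat, serialisable run configuration; CLI flags override file values."""

    workflow: str = "insilico"
    seed: int = 0
    out_dir: str = "near16s_out"
    params: dict[str, str] = field(default_factory=dict)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# near16s run configuration\n")
            fh.write(f"workflow = {self.workflow}\n")
            fh.write(f"seed = {self.seed}\n")
            fh.write(f"out_dir = {self.out_dir}\n")
            for key in sorted(self.params):
                fh.write(f"{key} = {self.params[key]}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "workflow":
                    cfg.workflow = value
                elif key == "seed":
                    cfg.seed = int(value)
                elif key == "out_dir":
                    cfg.out_dir = value
                else:
                    cfg.params[key] = value
        return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def load_genomes_dir(genomes_dir: str | Path) -> tuple[list, dict, primer_regions.PrimerSet]:
    """Load a community directory: per-assembly .fna/.gff pairs plus
    lineage.tsv and primers.tsv."""
    genomes_dir = Path(genomes_dir)
    lineage_path = genomes_dir / "lineage.tsv"
    primer_path = genomes_dir / "primers.tsv"
    for p in (lineage_path, primer_path):
        if not p.exists():
            raise FileNotFoundError(p)
    lineage_rows = {r["assembly_id"]: r for r in genome_io.read_lineage_table(lineage_path)}
    primer_set = primer_regions.PrimerSet.from_tsv(primer_path)
    genomes = []
    for fasta in sorted(genomes_dir.glob("*.fna")):
        gff = fasta.with_suffix(".gff")
        row = lineage_rows.get(fasta.stem)
        genomes.append(genome_io.parse_genome(fasta, gff, row))
    return genomes, lineage_rows, primer_set


def run_insilico(config: RunConfig) -> dict[str, Path]:
    """Execute extract -> regions -> entropy -> identifiability -> otus ->
    classify-cv on a genomes directory; write reports and an input manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.params
    genomes_dir = Path(params.get("genomes_dir", ""))
    upstream_len = int(params.get("upstream_len", genome_io.DEFAULT_UPSTREAM_LEN))
    max_mismatches = int(params.get("max_mismatches", primer_regions.DEFAULT_MAX_MISMATCHES))
    region_specs = params.get("regions", "V1V2,gene,upstream400+V1V2").split(",")
    thresholds = [
        float(x) for x in params.get("thresholds", "0.95,0.96,0.97,0.98,0.99").split(",")
    ]
    paths: dict[str, Path] = {}

    # extract (the primer table belongs to the regions stage)
    if not (genomes_dir / "primers.tsv").exists():
        raise StageError("regions", f"missing primer table {genomes_dir / 'primers.tsv'}")
    try:
        genomes, lineage_rows, primer_set = load_genomes_dir(genomes_dir)
        if not genomes:
            raise FileNotFoundError(f"no .fna assemblies under {genomes_dir}")
    except (FileNotFoundError, genome_io.MissingAssemblyError) as exc:
        raise StageError("extract", str(exc)) from exc
    all_loci = []
    for genome in genomes:
        loci, _ = genome_io.extract_linked_loci(genome, upstream_len=upstream_len)
        all_loci.extend(loci)

    # regions
    try:
        region_maps: dict[str, primer_regions.RegionMap] = {}
        rejected: list[str] = []
        for locus in all_loci:
            hits = primer_regions.find_primer_hits(
                locus.gene_seq, primer_set, max_mismatches=max_mismatches
            )
            try:
                region_maps[locus.locus_id] = primer_regions.qc_and_split(
                    locus.gene_seq, hits, primer_set.names, locus_id=locus.locus_id
                )
            except primer_regions.RegionQCError:
                rejected.append(locus.locus_id)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("regions", str(exc)) from exc
    loci, audit = genome_io.filter_dataset(all_loci, genomes, rejected)
    genome_io.write_audit_log(audit, out_dir / "audit.jsonl")
    paths["audit"] = out_dir / "audit.jsonl"
    primer_regions.write_region_table(
        [region_maps[l.locus_id] for l in loci if l.locus_id in region_maps],
        out_dir / "regions.tsv",
    )
    paths["regions"] = out_dir / "regions.tsv"

    lineages = {aid: dict(row) for aid, row in lineage_rows.items()}

    # entropy (per genus, upstream region)
    table = identifiability.composite_table(
        loci, region_maps, lineages, identifiability.RegionSpec(upstream_len=upstream_len)
    )
    entropy_means = conservation.rank_entropy_distribution(
        table, member_col="genus", sub_member_col="species", seed=config.seed
    )
    (out_dir / "entropy.json").write_text(json.dumps(entropy_means, indent=2))
    paths["entropy"] = out_dir / "entropy.json"

    # identifiability per region spec and level
    ident_report: dict[str, dict] = {}
    for spec_text in region_specs:
        spec = identifiability.RegionSpec.parse(spec_text)
        tab = identifiability.composite_table(loci, region_maps, lineages, spec)
        ident_report[spec_text] = {
            level: identifiability.copy_identifiability(
                tab, level, seed=config.seed
            ).mean_fraction
            for level in ("intra_strain", "inter_strain", "inter_species")
        }
        ident_report[spec_text]["strain_identifiability"] = (
            identifiability.strain_identifiability(tab)
        )
    (out_dir / "identifiability.json").write_text(json.dumps(ident_report, indent=2))
    paths["identifiability"] = out_dir / "identifiability.json"

    # OTU metrics on the first region spec
    spec = identifiability.RegionSpec.parse(region_specs[0])
    tab = identifiability.composite_table(loci, region_maps, lineages, spec)
    argmax, metrics = otu_metrics.optimal_threshold_sweep(tab, thresholds, seed=config.seed)
    metrics.to_csv(out_dir / "otu_metrics.tsv", sep="\t", index=False)
    (out_dir / "otu_argmax.json").write_text(json.dumps(argmax, indent=2))
    paths["otu_metrics"] = out_dir / "otu_metrics.tsv"

    # classification accuracy per region spec
    acc_report = {}
    for spec_text in region_specs:
        spec = identifiability.RegionSpec.parse(spec_text)
        tab = identifiability.composite_table(loci, region_maps, lineages, spec)
        try:
            report = taxon_classifier.leave_clade_out_cv(tab, seed=config.seed)
            acc_report[spec_text] = {
                "folds": report.folds,
                "mean_accuracy": report.mean_accuracy,
            }
        except ValueError as exc:
            acc_report[spec_text] = {"error": str(exc)}
    (out_dir / "classification.json").write_text(json.dumps(acc_report, indent=2))
    paths["classification"] = out_dir / "classification.json"

    # manifest of input hashes
    manifest = {
        str(p.relative_to(genomes_dir)): _sha256(p)
        for p in sorted(genomes_dir.iterdir())
        if p.is_file()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = out_dir / "manifest.json"
    return paths


def run_read_pipeline(
    pairs: Sequence[pipeline_core.ReadPair],
    primer: str,
    reference_catalog: Sequence[tuple[str, str, str]] | None = None,
    contigs_for_clusters: Callable[[Sequence[set[str]], Sequence[bool]], list] | None = None,
    min_len: int = pipeline_core.DEFAULT_MIN_READ_LEN,
    d_quant: int = 1,
    d_assembly: int = 2,
    prefix_a: int = pipeline_core.PREFIX_A,
    min_cluster_frac: float = pipeline_core.DEFAULT_MIN_CLUSTER_FRAC,
) -> dict:
    """Run the bespoke read-processing stages end to end.

    Stages: preprocess -> merge -> dereplicate + swarm (d=1, merged reads)
    -> prefix clustering (d=2, first ``prefix_a`` bases of R1) -> linkage ->
    a_f abundance -> (optionally) contig cleanup and copy-number calling.
    ``contigs_for_clusters`` supplies assembled contigs per a-cluster (from
    any assembler, or simulator-truth-derived); without it the contig
    stages are skipped.
    """
    report: dict = {"counts": {}}
    filtered, counts = pipeline_core.preprocess_reads(pairs, primer, min_len=min_len)
    report["counts"]["preprocess"] = counts
    merged = pipeline_core.merge_overlaps(filtered)
    n_merged = sum(1 for p in merged if p.merged_seq)
    report["counts"]["merged"] = n_merged
    if not merged:
        report.update({"a_f": {}, "copy_numbers": {}, "linkage": None, "contigs": None})
        return report

    # b: deduplicated merged-read clusters (quantification path, d=1)
    names_by_merged: dict[str, list[str]] = {}
    for p in merged:
        if p.merged_seq:
            names_by_merged.setdefault(p.merged_seq, []).append(p.read_id)
    b_clusters = pipeline_core.read_clusters(names_by_merged, d=d_quant) if names_by_merged else []

    # a: forward-prefix clusters over all filtered pairs (assembly path, d=2)
    names_by_prefix: dict[str, list[str]] = {}
    for p in merged:
        names_by_prefix.setdefault(p.r1_seq[:prefix_a].upper(), []).append(p.read_id)
    a_clusters = pipeline_core.read_clusters(names_by_prefix, d=d_assembly)

    linkage = pipeline_core.link_clusterings(
        b_clusters, a_clusters, total_pairs=len(merged), min_cluster_frac=min_cluster_frac
    )
    report["linkage"] = linkage
    report["a_f"] = pipeline_core.abundance_af(linkage) if b_clusters else {}

    if contigs_for_clusters is None:
        report["contigs"] = None
        report["copy_numbers"] = {}
        return report

    raw_contigs = contigs_for_clusters(linkage.a_clusters, linkage.a_below_threshold)
    by_cluster: dict[int, list] = {}
    for c in raw_contigs:
        by_cluster.setdefault(c.source_cluster, []).append(c)
    cleaned: list = []
    cleanup_log: list[dict] = []
    for ci in sorted(by_cluster):
        cs = pipeline_core.cleanup_within_cluster(by_cluster[ci])
        cleaned.extend(cs.contigs)
        cleanup_log.extend({"cluster": ci, **entry} for entry in cs.cleanup_log)
    if reference_catalog is not None:
        final = pipeline_core.cleanup_global(cleaned, reference_catalog)
        cleanup_log.extend(final.cleanup_log)
    else:
        final = pipeline_core.ContigSet(contigs=cleaned)
    final.cleanup_log = cleanup_log
    report["contigs"] = final
    report["copy_numbers"] = pipeline_core.call_copy_number(final, "genus")
    return report


def cluster_genus_map(report: Mapping) -> dict[int, str]:
    """Map each a-cluster to the genus of its retained contigs."""
    contigs = report.get("contigs")
    if contigs is None:
        return {}
    return {c.source_cluster: c.genus for c in contigs.contigs if c.genus}


def genome_abundance_estimates(
    report: Mapping,
    genus_of_cluster: Mapping[int, str],
) -> pd.DataFrame:
    """Aggregate a_f per genus and correct by called copy number.

    Returns a frame with columns genus, read_share (sum of a_f over the
    genus's OTUs) and corrected_abundance (read share / called copy number,
    renormalised).
    """
    af = report["a_f"]
    copy_numbers = report["copy_numbers"]
    share: dict[str, float] = {}
    for ci, value in af.items():
        genus = genus_of_cluster.get(ci)
        if genus is None:
            continue
        share[genus] = share.get(genus, 0.0) + value
    rows = []
    for genus in sorted(share):
        copies = copy_numbers.get(genus, 1) or 1
        rows.append(
            {"genus": genus, "read_share": share[genus], "corrected": share[genus] / copies}
        )
    df = pd.DataFrame(rows)
    if not df.empty and df["corrected"].sum() > 0:
        df["corrected_abundance"] = df["corrected"] / df["corrected"].sum()
    else:
        df["corrected_abundance"] = float("nan")
    return df.drop(columns=["corrected"])
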