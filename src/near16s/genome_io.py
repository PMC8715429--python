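"""Annotated-genome input and 16S/near-16S locus extraction.

Reads bacterial genome assemblies (FASTA + GFF3), pulls out 16S rRNA genes
together with the genomic region immediately upstream of each gene copy
(the "near-16S" region, in gene orientation), and applies the dataset
construction filters: gene-length bounds, wildcard removal, taxonomy
completeness, and whole-genome removal on per-locus QC failure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import reverse_complement

PRODUCT_PATTERN = re.compile(r"16S ribosomal RNA.*")

DEFAULT_UPSTREAM_LEN = 1000
MIN_GENE_LEN = 1000
MAX_GENE_LEN = 2000

_ACGT = frozenset("ACGT")


class MissingAssemblyError(FileNotFoundError):
    """Raised when an assembly's FASTA or annotation file is missing or empty."""


class AnnotationParseError(ValueError):
    """Raised on malformed annotation coordinates; names the offending line."""


@dataclass(frozen=True)
class Lineage:
    genus: str = ""
    species: str = ""
    strain: str = ""

    @property
    def complete(self) -> bool:
        """Genus and species both specified."""
        return bool(self.genus) and bool(self.species)


@dataclass(frozen=True)
class Feature:
    """One annotated feature in 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str


@dataclass
class GenomeRecord:
    assembly_id: str
    contigs: dict[str, str]
    features: list[Feature]
    lineage: Lineage = field(default_factory=Lineage)


@dataclass
class LinkedLocus:
    """One 16S gene copy joined to its upstream region, both 5'->3' in gene
    orientation; ``upstream_seq`` ends at the gene start."""

    locus_id: str
    assembly_id: str
    gene_seq: str
    upstream_seq: str
    upstream_truncated: bool = False


def _parse_gff3_features(path: str | Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationParseError(
                    f"line {line_no}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig_id, _source, _ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {line_no}: non-integer coordinates {start_s!r}..{end_s!r}"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationParseError(
                    f"line {line_no}: invalid coordinate range {start1}..{end1}"
                )
            product = ""
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key.strip() in ("product", "Name"):
                    product = value.strip()
                    break
            # GFF3 is 1-based closed; internal convention 0-based half-open.
            features.append(Feature(contig_id, start1 - 1, end1, strand, product))
    return features


def parse_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    lineage_row: Mapping[str, str] | None = None,
) -> GenomeRecord:
    """Parse one annotated assembly, retaining 16S rRNA features only.

    Features are retained when their product/Name attribute matches the
    case-sensitive pattern ``16S ribosomal RNA.*``. ``lineage_row`` is a
    mapping with keys ``assembly_id``, ``genus``, ``species``, ``strain``
    (a row of the lineage TSV).
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    for p in (fasta_path, annotation_path):
        if not p.exists() or p.stat().st_size == 0:
            raise MissingAssemblyError(f"missing-assembly: {p}")

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise MissingAssemblyError(f"missing-assembly: no FASTA records in {fasta_path}")

    features = []
    for feat in _parse_gff3_features(annotation_path):
        if not PRODUCT_PATTERN.match(feat.product):
            continue
        if feat.contig_id not in contigs:
            raise AnnotationParseError(
                f"feature on unknown contig {feat.contig_id!r}"
            )
        if feat.end > len(contigs[feat.contig_id]):
            raise AnnotationParseError(
                f"feature {feat.start}..{feat.end} exceeds contig "
                f"{feat.contig_id!r} length {len(contigs[feat.contig_id])}"
            )
        if feat.strand not in ("+", "-"):
            raise AnnotationParseError(f"feature strand {feat.strand!r} not in +/-")
        features.append(feat)

    row = lineage_row or {}
    lineage = Lineage(
        genus=str(row.get("genus", "") or ""),
        species=str(row.get("species", "") or ""),
        strain=str(row.get("strain", "") or ""),
    )
    assembly_id = str(row.get("assembly_id", "")) or fasta_path.stem
    return GenomeRecord(assembly_id, contigs, features, lineage)


def extract_linked_loci(
    genome: GenomeRecord,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
    min_gene_len: int = MIN_GENE_LEN,
    max_gene_len: int = MAX_GENE_LEN,
) -> tuple[list[LinkedLocus], int]:
    """Extract each retained 16S feature as a LinkedLocus.

    Genes outside [min_gene_len, max_gene_len] are dropped and counted
    (second return value). For "-"-strand genes, both gene and upstream are
    reverse-complemented; "upstream" is then the genomically 3' side. The
    ``upstream_truncated`` flag marks loci whose contig ends before
    ``upstream_len`` bases of upstream are available.
    """
    if upstream_len <= 0:
        raise ValueError("upstream_len must be positive")
    loci: list[LinkedLocus] = []
    n_len_discarded = 0
    for i, feat in enumerate(genome.features):
        contig = genome.contigs[feat.contig_id]
        gene_len = feat.end - feat.start
        if gene_len < min_gene_len or gene_len > max_gene_len:
            n_len_discarded += 1
            continue
        if feat.strand == "+":
            gene = contig[feat.start:feat.end]
            up_start = max(0, feat.start - upstream_len)
            upstream = contig[up_start:feat.start]
        else:
            gene = reverse_complement(contig[feat.start:feat.end])
            up_end = min(len(contig), feat.end + upstream_len)
            upstream = reverse_complement(contig[feat.end:up_end])
        loci.append(
            LinkedLocus(
                locus_id=f"{genome.assembly_id}|{feat.contig_id}|{i}",
                assembly_id=genome.assembly_id,
                gene_seq=gene,
                upstream_seq=upstream,
                upstream_truncated=len(upstream) < upstream_len,
            )
        )
    return loci, n_len_discarded


def filter_dataset(
    loci: Sequence[LinkedLocus],
    genomes: Sequence[GenomeRecord],
    qc_rejected_locus_ids: Iterable[str] = (),
) -> tuple[list[LinkedLocus], list[dict]]:
    """Apply the dataset filters and return (retained loci, audit log).

    Steps, in order:
      1. wildcard removal - any locus whose gene or upstream contains a
         non-ACGT letter is discarded;
      2. taxonomy - genomes lacking genus or species lose all their loci;
      3. whole-genome removal - a genome with at least one locus discarded in
         step 1 or rejected by primer QC (``qc_rejected_locus_ids``) loses
         all of its remaining loci.

    The audit log records per-step input/discard/output counts so that
    retained = input - sum(discards).
    """
    audit: list[dict] = []
    current = list(loci)
    lineage_by_assembly = {g.assembly_id: g.lineage for g in genomes}
    rejected = set(qc_rejected_locus_ids)

    flagged_assemblies: set[str] = set()

    def _log(step: str, n_in: int, n_drop: int) -> None:
        audit.append({"step": step, "input": n_in, "discarded": n_drop, "output": n_in - n_drop})

    # 1. wildcard removal
    n_in = len(current)
    kept = []
    for loc in current:
        if set(loc.gene_seq) <= _ACGT and set(loc.upstream_seq) <= _ACGT:
            kept.append(loc)
        else:
            flagged_assemblies.add(loc.assembly_id)
    _log("wildcard_removal", n_in, n_in - len(kept))
    current = kept

    # 2. taxonomy completeness
    n_in = len(current)
    kept = []
    for loc in current:
        lineage = lineage_by_assembly.get(loc.assembly_id)
        if lineage is not None and lineage.complete:
            kept.append(loc)
    _log("taxonomy_filter", n_in, n_in - len(kept))
    current = kept

    # 3. whole-genome removal on any per-locus discard (wildcard or primer QC)
    for loc in loci:
        if loc.locus_id in rejected:
            flagged_assemblies.add(loc.assembly_id)
    n_in = len(current)
    kept = [
        loc
        for loc in current
        if loc.assembly_id not in flagged_assemblies and loc.locus_id not in rejected
    ]
    _log("whole_genome_removal", n_in, n_in - len(kept))
    current = kept

    return current, audit


def write_audit_log(audit: Sequence[Mapping], path: str | Path) -> None:
    """Write the audit log as JSON lines."""
    with open(path, "w") as fh:
        for entry in audit:
            fh.write(json.dumps(dict(entry)) + "\n")


def read_lineage_table(path: str | Path) -> list[dict[str, str]]:
    """Read a lineage TSV with header assembly_id, genus, species, strain."""
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"assembly_id", "genus", "species", "strain"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"lineage table must have columns {sorted(required)}")
        return [dict(row) for row in reader]
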