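"""Synthetic annotated genomes and semi-targeted read simulation.

Generates communities of multi-operon bacterial genomes whose 16S genes
descend from one ancestral template down a genus -> species -> strain tree,
with separately controlled substitution rates for the gene's hypervariable
windows and for the upstream (near-16S) region, plus per-copy intragenomic
SNPs. The gene template carries nine conserved primer-binding sites flanking
the variable windows, so the primer-location machinery recovers every region
exactly on unmutated sites.

Upstream structure: the ``leader_len`` bases adjacent to the gene start form
a shared leader inherited down the tree; beyond the leader, each gene copy
of a species by default carries its own distal upstream context (drawn once
per copy slot at the species level), modelling the fact that distinct rRNA
operons sit in unrelated genomic neighbourhoods. Setting
``copy_context=False`` instead inherits a single upstream sequence for all
copies, so copies differ only through intragenomic SNPs.

Read simulation follows the chain-termination chemistry: a single primer
annealing between V2 and V3 is extended toward the upstream region, and
after each incorporated base synthesis terminates with probability p, so
fragment extension lengths are geometric with mean 1/p. R1 reads the
fragment from the priming site (through V2 and V1 into the upstream
region); R2 reads back from the termination point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .genome_io import Feature, GenomeRecord, Lineage
from .pipeline_core import Contig, ReadPair
from .primer_regions import Primer, PrimerSet

_BASES = np.array(list("ACGT"))

# gene template layout: V1 p1 V2 p2 ... V9 p9 tail. V1+p1+V2 = 341 so that
# the V1-V2 composite matches the published 341 bp scale.
_VAR_WIDTHS = (90, 231, 120, 140, 100, 110, 120, 100, 90)
_PRIMER_LEN = 20
_TAIL_LEN = 160
_FLANK = 2000  # minimum spacing around each operon


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community.

    Rates are substitutions per site on the mutable positions (hypervariable
    windows for the gene; the whole upstream region otherwise) and must lie
    in [0, 0.3]. ``copies_per_genome`` is a single int or one int per genome
    (genomes enumerate genus x species x strain in order).
    """

    n_genera: int = 6
    species_per_genus: int = 3
    strains_per_species: int = 3
    copies_per_genome: int | Sequence[int] = 4
    gene_rates: Mapping[str, float] = field(
        default_factory=lambda: {"genus": 0.02, "species": 0.005, "strain": 2e-4}
    )
    upstream_rates: Mapping[str, float] = field(
        default_factory=lambda: {"genus": 0.10, "species": 0.025, "strain": 1e-3}
    )
    intragenomic_snp_rate: float = 2e-4
    upstream_len: int = 1000
    leader_len: int = 200
    copy_context: bool = True
    abundance_profile: Sequence[float] | None = None
    genome_length: int | None = None
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return self.n_genera * self.species_per_genus * self.strains_per_species

    def validate(self) -> None:
        for rates in (self.gene_rates, self.upstream_rates):
            for rank, rate in rates.items():
                if not 0 <= rate <= 0.3:
                    raise ValueError(f"rate {rate} for {rank} outside [0, 0.3]")
        if not 0 <= self.intragenomic_snp_rate <= 0.3:
            raise ValueError("intragenomic_snp_rate outside [0, 0.3]")
        if self.abundance_profile is not None:
            prof = np.asarray(self.abundance_profile, dtype=float)
            if len(prof) != self.n_genomes:
                raise ValueError("abundance_profile length != number of genomes")
            if not np.isclose(prof.sum(), 1.0):
                raise ValueError("abundances must sum to 1")


@dataclass
class OperonTruth:
    assembly_id: str
    genus: str
    species: str
    strain: str
    locus_id: str
    contig_id: str
    strand: str
    gene_start: int
    gene_end: int
    upstream_seq: str
    gene_seq: str


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated community."""

    operons: list[OperonTruth]
    copy_numbers: dict[str, int]
    abundances: dict[str, float]
    lineages: dict[str, dict[str, str]]
    st16s_primer: str  # extension primer, 5'->3', anneals between V2 and V3
    priming_site_end: int  # gene coordinate of the primer-covered site's end

    def molecule(self, op: OperonTruth) -> str:
        """Full extension product of one operon: primer through the entire
        upstream region (5'->3' of the synthesized strand)."""
        return reverse_complement(op.upstream_seq + op.gene_seq[: self.priming_site_end])

    def operon_by_locus(self) -> dict[str, OperonTruth]:
        return {op.locus_id: op for op in self.operons}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(seq: str, positions: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    """Substitute each listed position independently with probability rate."""
    if rate <= 0 or positions.size == 0:
        return seq
    hit = positions[rng.random(positions.size) < rate]
    if hit.size == 0:
        return seq
    chars = np.array(list(seq))
    for pos in hit:
        current = chars[pos]
        alternatives = [b for b in "ACGT" if b != current]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _build_template(rng: np.random.Generator) -> tuple[str, PrimerSet, np.ndarray, int]:
    """(gene template, primer set, mutable gene positions, priming-site end)."""
    parts: list[str] = []
    primers: list[Primer] = []
    var_positions: list[int] = []
    pos = 0
    for i, width in enumerate(_VAR_WIDTHS):
        window = _random_seq(rng, width)
        parts.append(window)
        var_positions.extend(range(pos, pos + width))
        pos += width
        site = _random_seq(rng, _PRIMER_LEN)
        parts.append(site)
        primers.append(Primer(f"V{i + 1}", site))
        pos += _PRIMER_LEN
    parts.append(_random_seq(rng, _TAIL_LEN))
    template = "".join(parts)
    # priming site for the semi-targeted assay: the conserved site between V2
    # and V3 (the "V2" primer site); extension reads toward the gene start.
    priming_site_end = _VAR_WIDTHS[0] + _PRIMER_LEN + _VAR_WIDTHS[1] + _PRIMER_LEN
    return template, PrimerSet(primers), np.array(var_positions), priming_site_end


def generate_community(spec: CommunitySpec) -> tuple[list[GenomeRecord], SimTruth, PrimerSet]:
    """Generate annotated genomes plus ground truth for a community spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_template, primer_set, var_positions, priming_end = _build_template(rng)
    upstream_root = _random_seq(rng, spec.upstream_len)
    up_positions = np.arange(spec.upstream_len)
    distal_len = spec.upstream_len - spec.leader_len

    n_genomes = spec.n_genomes
    if isinstance(spec.copies_per_genome, int):
        copies = [spec.copies_per_genome] * n_genomes
    else:
        copies = list(spec.copies_per_genome)
        if len(copies) != n_genomes:
            raise ValueError("copies_per_genome list length != number of genomes")
    if spec.abundance_profile is None:
        abundances = [1.0 / n_genomes] * n_genomes
    else:
        abundances = list(map(float, spec.abundance_profile))

    genomes: list[GenomeRecord] = []
    truth = SimTruth(
        operons=[],
        copy_numbers={},
        abundances={},
        lineages={},
        st16s_primer=reverse_complement(
            gene_template[priming_end - _PRIMER_LEN : priming_end]
        ),
        priming_site_end=priming_end,
    )

    genome_idx = 0
    for gi in range(spec.n_genera):
        genus = f"Genus{gi:02d}"
        gene_g = _mutate(gene_template, var_positions, spec.gene_rates["genus"], rng)
        up_g = _mutate(upstream_root, up_positions, spec.upstream_rates["genus"], rng)
        for si in range(spec.species_per_genus):
            species = f"{genus} species{si:02d}"
            gene_s = _mutate(gene_g, var_positions, spec.gene_rates["species"], rng)
            up_s = _mutate(up_g, up_positions, spec.upstream_rates["species"], rng)
            max_copies = max(
                copies[genome_idx + k] for k in range(spec.strains_per_species)
            )
            if spec.copy_context:
                contexts = [_random_seq(rng, distal_len) for _ in range(max_copies)]
            else:
                contexts = [up_s[:distal_len]] * max_copies
            leader = up_s[distal_len:]
            for ti in range(spec.strains_per_species):
                strain = f"{species} strain{ti:02d}"
                assembly_id = f"GEN{genome_idx:04d}"
                n_copies = copies[genome_idx]
                gene_t = _mutate(gene_s, var_positions, spec.gene_rates["strain"], rng)
                operon_seqs = []
                for ci in range(n_copies):
                    up_copy = _mutate(
                        contexts[ci] + leader,
                        up_positions,
                        spec.upstream_rates["strain"],
                        rng,
                    )
                    up_copy = _mutate(
                        up_copy, up_positions, spec.intragenomic_snp_rate, rng
                    )
                    gene_copy = _mutate(
                        gene_t, var_positions, spec.intragenomic_snp_rate, rng
                    )
                    operon_seqs.append((up_copy, gene_copy))

                op_len = spec.upstream_len + len(gene_template)
                slot = op_len + 2 * _FLANK
                needed = _FLANK + n_copies * slot
                genome_len = spec.genome_length or needed
                if genome_len < needed:
                    raise ValueError(
                        f"genome_length {genome_len} too short for {n_copies} operons"
                    )
                contig = list(_random_seq(rng, genome_len))
                contig_id = f"{assembly_id}_chr"
                features: list[Feature] = []
                for ci, (up_copy, gene_copy) in enumerate(operon_seqs):
                    pos = _FLANK + ci * slot
                    strand = "+" if rng.random() < 0.5 else "-"
                    if strand == "+":
                        block = up_copy + gene_copy
                        gene_start = pos + len(up_copy)
                        gene_end = gene_start + len(gene_copy)
                    else:
                        block = reverse_complement(up_copy + gene_copy)
                        gene_start = pos
                        gene_end = pos + len(gene_copy)
                    contig[pos : pos + len(block)] = list(block)
                    features.append(
                        Feature(contig_id, gene_start, gene_end, strand, "16S ribosomal RNA")
                    )
                    truth.operons.append(
                        OperonTruth(
                            assembly_id=assembly_id,
                            genus=genus,
                            species=species,
                            strain=strain,
                            locus_id=f"{assembly_id}|{contig_id}|{ci}",
                            contig_id=contig_id,
                            strand=strand,
                            gene_start=gene_start,
                            gene_end=gene_end,
                            upstream_seq=up_copy,
                            gene_seq=gene_copy,
                        )
                    )
                genomes.append(
                    GenomeRecord(
                        assembly_id=assembly_id,
                        contigs={contig_id: "".join(contig)},
                        features=features,
                        lineage=Lineage(genus=genus, species=species, strain=strain),
                    )
                )
                truth.copy_numbers[assembly_id] = n_copies
                truth.abundances[assembly_id] = abundances[genome_idx]
                truth.lineages[assembly_id] = {
                    "genus": genus,
                    "species": species,
                    "strain": strain,
                }
                genome_idx += 1
    return genomes, truth, primer_set


def simulate_st16s_reads(
    truth: SimTruth,
    termination_prob: float = 0.002,
    read_len: int = 300,
    n_pairs: int = 5000,
    error_rate: float = 0.001,
    seed: int = 0,
    quality_char: str = "?",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate semi-targeted paired reads with ground-truth provenance.

    Operons are sampled proportionally to genome abundance x copy number
    (uniform over copies within a genome). Per fragment, extension beyond
    the primer terminates after each incorporated base with probability p,
    capped at the template end; R1 = the first ``read_len`` bases of the
    molecule (primer + extension), R2 = ``read_len`` bases from the
    termination end reading back. Substitution errors are uniform at
    ``error_rate``; qualities are constant.
    """
    if not 0 < termination_prob < 1:
        raise ValueError("termination_prob must be in (0, 1)")
    rng = np.random.default_rng(seed)
    operons = truth.operons
    # one weight per operon copy: a genome's total sampling mass is then
    # abundance x copy number, as for physical template molecules
    weights = np.array(
        [truth.abundances[op.assembly_id] for op in operons], dtype=float
    )
    weights /= weights.sum()
    templates = [truth.molecule(op) for op in operons]

    choices = rng.choice(len(operons), size=n_pairs, p=weights)
    extensions = rng.geometric(termination_prob, size=n_pairs)
    pairs: list[ReadPair] = []
    prov_rows = []
    primer_len = len(truth.st16s_primer)
    for i in range(n_pairs):
        oi = int(choices[i])
        template = templates[oi]
        frag_len = min(primer_len + int(extensions[i]), len(template))
        fragment = template[:frag_len]
        r1 = fragment[:read_len]
        r2 = reverse_complement(fragment)[:read_len]
        r1 = _add_errors(r1, error_rate, rng)
        r2 = _add_errors(r2, error_rate, rng)
        read_id = f"read{i:07d}"
        pairs.append(
            ReadPair(
                read_id=read_id,
                r1_seq=r1,
                r2_seq=r2,
                r1_qual=quality_char * len(r1),
                r2_qual=quality_char * len(r2),
            )
        )
        prov_rows.append(
            {
                "read_id": read_id,
                "assembly_id": operons[oi].assembly_id,
                "locus_id": operons[oi].locus_id,
                "fragment_len": frag_len,
            }
        )
    return pairs, pd.DataFrame(prov_rows)


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_mock_standard(
    preset: str = "even8",
    seed: int = 0,
    listeria_like_copies: int = 6,
) -> tuple[list[GenomeRecord], SimTruth, PrimerSet]:
    """Community emulating an even mock standard (8 or 20 members).

    Each member is its own genus with a single species and strain at equal
    abundance; copy numbers are drawn from 1..10 (seeded) with the first
    member fixed to a six-copy layout with all copies distinct in their
    distal upstream context.
    """
    if preset not in ("even8", "even20"):
        raise ValueError("preset must be 'even8' or 'even20'")
    n = 8 if preset == "even8" else 20
    rng = np.random.default_rng(seed)
    copies = [int(c) for c in rng.integers(1, 11, size=n)]
    copies[0] = listeria_like_copies
    spec = CommunitySpec(
        n_genera=n,
        species_per_genus=1,
        strains_per_species=1,
        copies_per_genome=copies,
        gene_rates={"genus": 0.05, "species": 0.0, "strain": 0.0},
        upstream_rates={"genus": 0.25, "species": 0.0, "strain": 0.0},
        intragenomic_snp_rate=2e-4,
        copy_context=True,
        abundance_profile=[1.0 / n] * n,
        seed=seed,
    )
    return generate_community(spec)


def truth_contigs(
    truth: SimTruth,
    cluster_reads: Sequence[set[str]],
    provenance: pd.DataFrame,
    skip_flags: Sequence[bool] | None = None,
) -> list[Contig]:
    """Ground-truth-derived contigs per linked read cluster.

    Stands in for an external assembler: for every read cluster (a-cluster),
    each source operon with at least one read contributes one contig - the
    operon's full extension product with the priming primer removed - with
    abundance equal to its read count in the cluster. Clusters flagged in
    ``skip_flags`` (below the assembly threshold) are skipped.
    """
    by_read = dict(zip(provenance["read_id"], provenance["locus_id"]))
    ops = truth.operon_by_locus()
    primer_len = len(truth.st16s_primer)
    contigs: list[Contig] = []
    for ci, reads in enumerate(cluster_reads):
        if skip_flags is not None and skip_flags[ci]:
            continue
        counts: dict[str, int] = {}
        for name in reads:
            locus = by_read.get(name)
            if locus is not None:
                counts[locus] = counts.get(locus, 0) + 1
        for locus, count in sorted(counts.items()):
            seq = truth.molecule(ops[locus])[primer_len:]
            contigs.append(
                Contig(
                    contig_id=f"cluster{ci}|{locus}",
                    seq=seq,
                    source_cluster=ci,
                    abundance=float(count),
                )
            )
    return contigs


def reference_catalog(truth: SimTruth) -> list[tuple[str, str, str]]:
    """Genus-labelled near-16S reference sequences derived from the
    community genomes (a stand-in for a labelled nucleotide database)."""
    primer_len = len(truth.st16s_primer)
    return [
        (op.locus_id, op.genus, truth.molecule(op)[primer_len:])
        for op in truth.operons
    ]


# ---------------------------------------------------------------------------
# writers


def write_community(
    genomes: Sequence[GenomeRecord],
    truth: SimTruth,
    primer_set: PrimerSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + GFF3 per genome, a lineage TSV, the primer TSV and the
    truth table; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    lineage_rows = []
    for genome in genomes:
        fasta = out_dir / f"{genome.assembly_id}.fna"
        gff = out_dir / f"{genome.assembly_id}.gff"
        with open(fasta, "w") as fh:
            for contig_id, seq in genome.contigs.items():
                fh.write(f">{contig_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for feat in genome.features:
                fh.write(
                    f"{feat.contig_id}\tnear16s_sim\trRNA\t{feat.start + 1}\t{feat.end}"
                    f"\t.\t{feat.strand}\t.\tproduct={feat.product}\n"
                )
        lineage_rows.append(
            {
                "assembly_id": genome.assembly_id,
                "genus": genome.lineage.genus,
                "species": genome.lineage.species,
                "strain": genome.lineage.strain,
            }
        )
        paths[f"fasta:{genome.assembly_id}"] = fasta
        paths[f"gff:{genome.assembly_id}"] = gff
    lineage_path = out_dir / "lineage.tsv"
    pd.DataFrame(lineage_rows).to_csv(lineage_path, sep="\t", index=False)
    paths["lineage"] = lineage_path
    primer_path = out_dir / "primers.tsv"
    primer_set.to_tsv(primer_path)
    paths["primers"] = primer_path
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(
        [
            {
                "assembly_id": op.assembly_id,
                "locus_id": op.locus_id,
                "genus": op.genus,
                "species": op.species,
                "strain": op.strain,
                "strand": op.strand,
                "gene_start": op.gene_start,
                "gene_end": op.gene_end,
                "copy_number": truth.copy_numbers[op.assembly_id],
                "abundance": truth.abundances[op.assembly_id],
            }
            for op in truth.operons
        ]
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def write_fastq(pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    import gzip

    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.read_id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")
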