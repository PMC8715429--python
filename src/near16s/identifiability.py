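"""Identifiability statistics for 16S gene copies and strains.

The central statistic: within each member of a taxonomic rank, the fraction
of identifiable gene copies is the number of distinct composite sequences
divided by the total number of copies, and the report's mean is the
arithmetic mean over members. A strain is identifiable within its species if
at least one of its copies carries a composite sequence seen in no other
strain of that species.

Composites are built from a :class:`RegionSpec` - e.g. the full gene, a run
of hypervariable regions such as V1-V2, or an upstream prefix of length L
concatenated with V1-V2 (the near-16S composite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .genome_io import LinkedLocus
from .primer_regions import RegionMap

DEFAULT_STRAINS_PER_SPECIES = 10
DEFAULT_SPECIES_PER_GENUS = 10

_SPEC_RE = re.compile(r"^upstream\(?(\d+)\)?$")


@dataclass(frozen=True)
class RegionSpec:
    """What to include in a composite sequence.

    ``upstream_len`` bases immediately 5' of the gene start (0 for none),
    plus either the full gene or a contiguous run of named regions.
    """

    upstream_len: int = 0
    full_gene: bool = False
    regions: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse e.g. "gene", "V4", "V1V2", "upstream400+V1V2"."""
        upstream_len = 0
        full_gene = False
        regions: list[str] = []
        for part in text.replace(" ", "").split("+"):
            m = _SPEC_RE.match(part)
            if m:
                upstream_len = int(m.group(1))
            elif part == "gene":
                full_gene = True
            elif part:
                regions.extend(re.findall(r"V\d+", part))
        return cls(upstream_len=upstream_len, full_gene=full_gene, regions=tuple(regions))

    def __str__(self) -> str:
        parts = []
        if self.upstream_len:
            parts.append(f"upstream{self.upstream_len}")
        if self.full_gene:
            parts.append("gene")
        parts.extend(self.regions)
        return "+".join(parts) or "empty"


def build_composite(
    locus: LinkedLocus,
    region_map: RegionMap | None,
    spec: RegionSpec,
) -> str:
    """Composite sequence of a locus under ``spec``.

    A contiguous run of regions spans from the first region's start through
    the start of the primer terminating the last region (so V1-V2 runs from
    the gene start to the start of the V2 primer site). The upstream prefix
    is the last ``upstream_len`` bases of the upstream region (those
    immediately adjacent to the gene start).
    """
    parts: list[str] = []
    if spec.upstream_len:
        parts.append(locus.upstream_seq[-spec.upstream_len:] if spec.upstream_len else "")
    if spec.full_gene:
        parts.append(locus.gene_seq)
    elif spec.regions:
        if region_map is None:
            raise ValueError("region_map required for region-based composites")
        start = min(region_map.regions[r][0] for r in spec.regions)
        end = max(region_map.hits[r].start for r in spec.regions)
        parts.append(locus.gene_seq[start:end])
    return "".join(parts).upper()


def composite_table(
    loci: Sequence[LinkedLocus],
    region_maps: Mapping[str, RegionMap],
    lineages: Mapping[str, Mapping[str, str]],
    spec: RegionSpec,
    exclude_truncated: bool = False,
) -> pd.DataFrame:
    """One row per locus: genus, species, strain, locus_id, sequence."""
    rows = []
    for locus in loci:
        if exclude_truncated and locus.upstream_truncated:
            continue
        lin = lineages[locus.assembly_id]
        rows.append(
            {
                "genus": lin["genus"],
                "species": lin["species"],
                "strain": lin["strain"],
                "locus_id": locus.locus_id,
                "sequence": build_composite(locus, region_maps.get(locus.locus_id), spec),
            }
        )
    return pd.DataFrame(rows, columns=["genus", "species", "strain", "locus_id", "sequence"])


@dataclass
class IdentifiabilityReport:
    level: str  # intra_strain | inter_strain | inter_species
    per_member: dict[str, float] = field(default_factory=dict)

    @property
    def mean_fraction(self) -> float:
        if not self.per_member:
            return float("nan")
        return float(np.mean(list(self.per_member.values())))


def _cap(rng: np.random.Generator, items: list, cap: int | None) -> list:
    if cap is None or len(items) <= cap:
        return items
    return sorted(rng.choice(items, size=cap, replace=False).tolist())


def copy_identifiability(
    table: pd.DataFrame,
    level: str,
    max_strains_per_species: int | None = DEFAULT_STRAINS_PER_SPECIES,
    max_species_per_genus: int | None = DEFAULT_SPECIES_PER_GENUS,
    seed: int = 0,
) -> IdentifiabilityReport:
    """Fraction of identifiable gene copies at a taxonomic level.

    ``table`` holds one row per gene copy with columns genus, species,
    strain, sequence. Grouping unit per level: the strain (intra_strain),
    the species pooling its strains' copies (inter_strain, species with
    >= 2 strains only), or the genus pooling its species (inter_species).
    Strains per species (all levels) and species per genus (inter_species)
    are capped by uniform sub-sampling with ``seed``. Pooling keeps the
    multiset of copies; no within-strain pre-deduplication.
    """
    if level not in ("intra_strain", "inter_strain", "inter_species"):
        raise ValueError(f"unknown level {level!r}")
    rng = np.random.default_rng(seed)

    # cap strains within each species (applies to every level)
    kept_rows = []
    for (genus, species), block in table.groupby(["genus", "species"], sort=True):
        strains = _cap(rng, sorted(block["strain"].unique()), max_strains_per_species)
        kept_rows.append(block[block["strain"].isin(strains)])
    df = pd.concat(kept_rows) if kept_rows else table

    report = IdentifiabilityReport(level=level)

    if level == "intra_strain":
        for (genus, species, strain), block in df.groupby(
            ["genus", "species", "strain"], sort=True
        ):
            if len(block) == 0:
                continue
            report.per_member[f"{genus}|{species}|{strain}"] = (
                block["sequence"].nunique() / len(block)
            )
    elif level == "inter_strain":
        for (genus, species), block in df.groupby(["genus", "species"], sort=True):
            if block["strain"].nunique() < 2 or len(block) == 0:
                continue
            report.per_member[f"{genus}|{species}"] = block["sequence"].nunique() / len(block)
    else:  # inter_species
        for genus, block in df.groupby("genus", sort=True):
            species = _cap(rng, sorted(block["species"].unique()), max_species_per_genus)
            pooled = block[block["species"].isin(species)]
            if len(pooled) == 0:
                continue
            report.per_member[str(genus)] = pooled["sequence"].nunique() / len(pooled)
    return report


def strain_identifiability(table: pd.DataFrame) -> dict[str, float]:
    """Fraction of identifiable strains per species (species with >= 2 strains).

    A strain is identifiable iff it has at least one copy whose composite
    sequence appears in no other strain of the same species.
    """
    result: dict[str, float] = {}
    for (genus, species), block in table.groupby(["genus", "species"], sort=True):
        strains = sorted(block["strain"].unique())
        if len(strains) < 2:
            continue
        n_ident = 0
        for strain in strains:
            own = set(block.loc[block["strain"] == strain, "sequence"])
            others = set(block.loc[block["strain"] != strain, "sequence"])
            if own - others:
                n_ident += 1
        result[f"{genus}|{species}"] = n_ident / len(strains)
    return result


def upstream_length_sweep(
    loci: Sequence[LinkedLocus],
    region_maps: Mapping[str, RegionMap],
    lineages: Mapping[str, Mapping[str, str]],
    lengths: Sequence[int],
    level: str = "intra_strain",
    base_regions: tuple[str, ...] = ("V1", "V2"),
    exclude_truncated: bool = True,
    seed: int = 0,
) -> dict[int, float]:
    """Mean copy identifiability as a function of upstream prefix length.

    Composite at length L = upstream_prefix(L) + the ``base_regions`` run.
    Loci whose available upstream is shorter than max(lengths) are excluded
    when ``exclude_truncated`` (otherwise their full available prefix is
    used). L = 0 reduces to the within-gene composite.
    """
    lengths = sorted(lengths)
    max_len = lengths[-1] if lengths else 0
    usable = [
        loc
        for loc in loci
        if not (exclude_truncated and len(loc.upstream_seq) < max_len)
    ]
    out: dict[int, float] = {}
    for L in lengths:
        spec = RegionSpec(upstream_len=L, regions=base_regions)
        table = composite_table(usable, region_maps, lineages, spec)
        out[L] = copy_identifiability(table, level, seed=seed).mean_fraction
    return out


def nearest_nonidentical_distances(
    seqs: Sequence[str],
    n_queries: int = 1000,
    k: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Edit distances from random query sequences to their k closest
    non-identical neighbours.

    Distance is Levenshtein (substitutions + indels); neighbours at distance
    0 (identical sequences) are skipped. Queries with fewer than k
    non-identical neighbours get a shorter list and ``short=True``.
    """
    if n_queries > len(seqs):
        raise ValueError("n_queries exceeds number of sequences")
    rng = np.random.default_rng(seed)
    query_idx = rng.choice(len(seqs), size=n_queries, replace=False)
    results = []
    for qi in query_idx:
        q = seqs[qi]
        dists = []
        for j, s in enumerate(seqs):
            if j == qi:
                continue
            d = edlib.align(q, s, mode="NW", task="distance")["editDistance"]
            if d > 0:
                dists.append(d)
        dists.sort()
        results.append(
            {"query_index": int(qi), "distances": dists[:k], "short": len(dists) < k}
        )
    return results
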