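"""Inter-region primer location and hypervariable-region splitting.

The 16S gene is tiled as V1 p1 V2 p2 ... V9 p9 tail, where p_k is a
conserved primer-binding site and each primer is named after the
hypervariable region immediately upstream (5') of its site. Locating all
primers on a gene copy therefore delimits the variable sub-regions; a locus
whose primers are missing or out of order fails QC and is rejected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
from Bio.Data.IUPACData import ambiguous_dna_values

DEFAULT_MAX_MISMATCHES = 2

# character-pair equivalences letting IUPAC-degenerate primer bases match any
# compatible target base without penalty
_IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (code, base)
    for code, bases in ambiguous_dna_values.items()
    if len(bases) > 1
    for base in bases
]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str


@dataclass
class PrimerSet:
    """Ordered 5'->3' list of inter-region primers (IUPAC codes allowed)."""

    entries: list[Primer]

    def __post_init__(self) -> None:
        names = [p.name for p in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("primer names must be unique")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrimerSet":
        entries = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "name":
                    continue
                entries.append(Primer(row[0], row[1].upper()))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tsequence\n")
            for p in self.entries:
                fh.write(f"{p.name}\t{p.sequence}\n")


@dataclass(frozen=True)
class PrimerHit:
    start: int  # 0-based half-open, within gene_seq
    end: int
    mismatches: int  # substitutions + indel columns
    score: int  # match +1, mismatch -2, gap -2


@dataclass
class RegionMap:
    locus_id: str
    hits: dict[str, PrimerHit] = field(default_factory=dict)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)


class RegionQCError(ValueError):
    """Locus rejected by primer QC; ``reason`` is a machine-readable code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _score_from_cigar(cigar: str) -> tuple[int, int]:
    """(score, edit columns) under match +1, mismatch -2, gap -2."""
    score = 0
    edits = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            score += n
        else:  # X, I, D
            score -= 2 * n
            edits += n
    return score, edits


def find_primer_hits(
    gene_seq: str,
    primer_set: PrimerSet,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> dict[str, PrimerHit]:
    """Best placement of each primer on ``gene_seq``.

    Placements are scored by infix (end-gaps free on the gene) alignment;
    the minimum-edit placement is kept, leftmost on ties, and reported with
    the blastn-short-like score (match +1, mismatch/gap -2). Primers whose
    best placement needs more than ``max_mismatches`` edit columns
    (substitutions + indels) are absent from the result. IUPAC degeneracies
    in the primer match compatible bases without penalty.
    """
    if not gene_seq:
        raise ValueError("gene_seq must be non-empty")
    hits: dict[str, PrimerHit] = {}
    for primer in primer_set.entries:
        res = edlib.align(
            primer.sequence,
            gene_seq,
            mode="HW",
            task="path",
            k=max_mismatches,
            additionalEqualities=_IUPAC_EQUALITIES,
        )
        if res["editDistance"] < 0:
            continue  # absent: > max_mismatches
        # leftmost among equal-distance placements
        start, end_incl = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
        score, edits = _score_from_cigar(res["cigar"])
        hits[primer.name] = PrimerHit(start=start, end=end_incl + 1, mismatches=edits, score=score)
    return hits


def qc_and_split(
    gene_seq: str,
    hits: Mapping[str, PrimerHit],
    primer_names: Sequence[str],
    locus_id: str = "",
) -> RegionMap:
    """QC primer hits and split the gene into hypervariable regions.

    Raises :class:`RegionQCError` with reason ``missing-primer:<name>``,
    ``non-sequential:<prev>><name>`` or ``empty-region:<name>``. Region V_k
    spans from the end of primer k-1's hit (gene start for the first) to the
    start of primer k's hit.
    """
    for name in primer_names:
        if name not in hits:
            raise RegionQCError(f"missing-primer:{name}")
    prev_end = 0
    prev_name = "gene-start"
    regions: dict[str, tuple[int, int]] = {}
    for name in primer_names:
        hit = hits[name]
        if hit.start < prev_end:
            raise RegionQCError(f"non-sequential:{prev_name}>{name}")
        if hit.start == prev_end:
            raise RegionQCError(f"empty-region:{name}")
        regions[name] = (prev_end, hit.start)
        prev_end = hit.end
        prev_name = name
    rm = RegionMap(locus_id=locus_id)
    rm.hits = dict(hits)
    rm.regions = regions
    return rm


def write_region_table(region_maps: Sequence[RegionMap], path: str | Path) -> None:
    """Per-locus region intervals as BED-like TSV (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tregion\tstart\tend\n")
        for rm in region_maps:
            for region, (start, end) in rm.regions.items():
                fh.write(f"{rm.locus_id}\t{region}\t{start}\t{end}\n")
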