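"""Bespoke computational stages of semi-targeted 16S read processing.

The semi-targeted library yields read pairs whose forward read (R1) starts
at a fixed priming site inside the 16S gene (reading through V2 and V1 into
the upstream region) while the reverse read (R2) starts at a random
chain-termination point in the upstream region. This module implements the
pipeline's own computation around those reads: pair filtering and primer
trimming, gapless overlap merging, exact dereplication, swarm-style
single-linkage d-clustering, linkage of the two clusterings, the a_f
abundance statistic, the two-level contig cleanup rules, and copy-number
calling from retained contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import reverse_complement

DEFAULT_MIN_READ_LEN = 250
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MIN_CLUSTER_FRAC = 0.001
PREFIX_A = 240  # forward-read prefix used for OTU clustering
PREFIX_CLEAN = 230  # contig prefix used in within-cluster cleanup


@dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str = ""
    r2_qual: str = ""
    merged_seq: str | None = None


@dataclass
class ClusterLinkage:
    """Two nested read clusterings: b-clusters (deduplicated merged-read
    clusters) and a-clusters (forward-prefix clusters)."""

    b_clusters: list[set[str]]
    a_clusters: list[set[str]]
    a_below_threshold: list[bool]  # not-for-assembly flags, parallel to a_clusters

    @property
    def j(self) -> int:
        return len(self.b_clusters)


@dataclass
class Contig:
    contig_id: str
    seq: str
    source_cluster: int
    abundance: float = 1.0
    genus: str | None = None


@dataclass
class ContigSet:
    contigs: list[Contig]
    cleanup_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read preprocessing and merging


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def preprocess_reads(
    pairs: Iterable[ReadPair],
    primer: str,
    min_len: int = DEFAULT_MIN_READ_LEN,
    r2_window: int = 40,
    r1_window: int = 50,
) -> tuple[list[ReadPair], dict[str, int]]:
    """Filter and primer-trim read pairs.

    Drops pairs where either read is shorter than ``min_len`` or contains N;
    drops pairs whose R2 carries the 16S primer (Hamming distance <= 1)
    anywhere within its first ``r2_window`` bases (these read back into the
    gene instead of the upstream region); trims the primer from R1 where it
    matches at edit distance <= 2 with the match starting within the first
    ``r1_window`` bases. Returns surviving pairs plus per-rule drop counts.
    """
    primer = primer.upper()
    counts = {"input": 0, "too_short": 0, "contains_n": 0, "r2_primer": 0, "kept": 0}
    kept: list[ReadPair] = []
    for pair in pairs:
        counts["input"] += 1
        r1 = pair.r1_seq.upper()
        r2 = pair.r2_seq.upper()
        if len(r1) < min_len or len(r2) < min_len:
            counts["too_short"] += 1
            continue
        if "N" in r1 or "N" in r2:
            counts["contains_n"] += 1
            continue
        window = r2[: r2_window + len(primer) - 1]
        if any(
            _hamming_at_most(primer, window[o : o + len(primer)], 1)
            for o in range(0, min(r2_window, len(window) - len(primer) + 1))
        ):
            counts["r2_primer"] += 1
            continue
        res = edlib.align(primer, r1[: r1_window + len(primer) + 2], mode="HW", task="locations", k=2)
        if res["editDistance"] >= 0:
            start, end_incl = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
            if start < r1_window:
                r1 = r1[end_incl + 1 :]
        kept.append(replace(pair, r1_seq=r1, r2_seq=r2, r1_qual=pair.r1_qual[len(pair.r1_seq) - len(r1):], merged_seq=None))
        counts["kept"] += 1
    return kept, counts


def _overlap_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def merge_overlaps(
    pairs: Iterable[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = 0.10,
    seed_len: int = 16,
) -> list[ReadPair]:
    """Join read pairs whose 3' ends overlap.

    The best gapless overlap between the R1 suffix and the reverse
    complement of R2 of length >= ``min_overlap`` with <= 10 % mismatches is
    accepted; disagreeing positions take the base with the higher quality
    score. Unmerged pairs pass through with ``merged_seq`` unset.
    """
    out: list[ReadPair] = []
    for pair in pairs:
        r1 = pair.r1_seq.upper()
        rc2 = reverse_complement(pair.r2_seq.upper())
        q1 = pair.r1_qual or "!" * len(r1)
        q2 = (pair.r2_qual or "!" * len(pair.r2_seq))[::-1]

        # candidate offsets in r1 where rc2 starts, from exact seed matches at
        # three positions of rc2 (robust to isolated sequencing errors); short
        # reads fall back to an exhaustive scan
        candidates: set[int] = set()
        for seed_off in (0, seed_len, 2 * seed_len):
            seed = rc2[seed_off : seed_off + seed_len]
            if len(seed) < seed_len:
                break
            pos = r1.find(seed)
            while pos != -1:
                if pos - seed_off >= 0:
                    candidates.add(pos - seed_off)
                pos = r1.find(seed, pos + 1)
        if not candidates and min(len(r1), len(rc2)) < 80:
            candidates = set(range(0, max(0, len(r1) - min_overlap + 1)))

        best: tuple[int, int, int] | None = None  # (score, overlap_len, offset)
        for off in sorted(candidates):
            ov = min(len(r1) - off, len(rc2))
            if ov < min_overlap:
                continue
            mm = _overlap_mismatches(r1[off : off + ov], rc2[:ov])
            if mm > max_mismatch_frac * ov:
                continue
            score = ov - 2 * mm
            cand = (score, ov, -off)
            if best is None or cand > best:
                best = cand
        if best is None:
            out.append(replace(pair, merged_seq=None))
            continue
        _, ov, neg_off = best
        off = -neg_off
        consensus = []
        for i in range(ov):
            b1, b2 = r1[off + i], rc2[i]
            if b1 == b2:
                consensus.append(b1)
            else:
                c1 = q1[off + i] if off + i < len(q1) else "!"
                c2 = q2[i] if i < len(q2) else "!"
                consensus.append(b1 if c1 >= c2 else b2)
        merged = r1[:off] + "".join(consensus) + rc2[ov:]
        out.append(replace(pair, merged_seq=merged))
    return out


# ---------------------------------------------------------------------------
# dereplication and swarm clustering


def dereplicate(seqs: Iterable[str]) -> list[tuple[str, int]]:
    """Exact dereplication after uppercasing; size-descending, ties lexicographic."""
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        counts[s] = counts.get(s, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def swarm_cluster(
    unique_seqs_with_sizes: Sequence[tuple[str, int]],
    d: int,
) -> list[list[tuple[str, int]]]:
    """Swarm-style clustering: single linkage at Levenshtein distance <= d.

    Iterative agglomeration from the largest-abundance seed to closure is
    equivalent to the connected components of the <= d-edit graph; clusters
    are ordered (and internally sorted) by abundance, ties lexicographic.
    d = 0 reduces to dereplication classes. Length bucketing prunes pairs
    whose length difference already exceeds d.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    items = list(unique_seqs_with_sizes)
    n = len(items)
    uf = _UnionFind(n)
    if d > 0:
        by_len: dict[int, list[int]] = {}
        for i, (s, _) in enumerate(items):
            by_len.setdefault(len(s), []).append(i)
        for L, idxs in by_len.items():
            partners = list(idxs)
            for dL in range(1, d + 1):
                partners += by_len.get(L + dL, [])
            for ai, i in enumerate(idxs):
                si = items[i][0]
                for j in partners:
                    if j <= i and len(items[j][0]) == L:
                        continue
                    if uf.find(i) == uf.find(j):
                        continue
                    res = edlib.align(si, items[j][0], mode="NW", task="distance", k=d)
                    if res["editDistance"] >= 0:
                        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members in groups.values():
        mem = sorted((items[i] for i in members), key=lambda kv: (-kv[1], kv[0]))
        clusters.append(mem)
    clusters.sort(key=lambda c: (-sum(sz for _, sz in c), c[0][0]))
    return clusters


def read_clusters(
    names_by_seq: Mapping[str, Sequence[str]],
    d: int,
) -> list[set[str]]:
    """Dereplicate + swarm a name->sequence inverse map into read-name sets.

    ``names_by_seq`` maps each unique sequence to the reads carrying it
    (abundance = number of reads).
    """
    uniques = sorted(
        ((seq, len(names)) for seq, names in names_by_seq.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    clusters = swarm_cluster(uniques, d)
    return [
        {name for seq, _ in cluster for name in names_by_seq[seq]} for cluster in clusters
    ]


def link_clusterings(
    b_clusters: Sequence[set[str]],
    a_clusters: Sequence[set[str]],
    total_pairs: int | None = None,
    min_cluster_frac: float = DEFAULT_MIN_CLUSTER_FRAC,
) -> ClusterLinkage:
    """Link the merged-read clustering (b) to the prefix clustering (a).

    a-clusters holding less than ``min_cluster_frac`` of the filtered read
    pairs are flagged not-for-assembly.
    """
    if total_pairs is None:
        total_pairs = len(set().union(*a_clusters)) if a_clusters else 0
    flags = [
        (len(a) / total_pairs if total_pairs else 0.0) < min_cluster_frac
        for a in a_clusters
    ]
    return ClusterLinkage(
        b_clusters=[set(b) for b in b_clusters],
        a_clusters=[set(a) for a in a_clusters],
        a_below_threshold=flags,
    )


def abundance_af(linkage: ClusterLinkage) -> dict[int, float]:
    """Per-a-cluster relative abundance a_f = (1/j) sum_b |b & a| / |b|."""
    j = linkage.j
    if j < 1:
        raise ValueError("at least one b-cluster required")
    for b in linkage.b_clusters:
        if not b:
            raise ValueError("empty b-cluster")
    out: dict[int, float] = {}
    for ai, a in enumerate(linkage.a_clusters):
        total = sum(len(b & a) / len(b) for b in linkage.b_clusters)
        out[ai] = total / j
    return out


# ---------------------------------------------------------------------------
# contig cleanup


def _infix_identity(query: str, target: str) -> tuple[float, float, str, str]:
    """Identity of ``query`` aligned as an infix of ``target``.

    Returns (identity, aligned_fraction_of_query, query_aligned,
    target_aligned); identity = matching columns / alignment columns with
    end-gaps on the target free.
    """
    if not query or not target:
        return 0.0, 0.0, "", ""
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    cols = len(qa)
    matches = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
    aligned_q = sum(1 for x in qa if x != "-")
    return (matches / cols if cols else 0.0), aligned_q / len(query), qa, ta


def cleanup_within_cluster(
    contigs: Sequence[Contig],
    prefix_len: int = PREFIX_CLEAN,
    prefix_identity: float = 0.96,
    min_len_frac: float = 0.52,
    containment_identity: float = 0.98,
    containment_frac: float = 0.90,
    tail_exclude: int = 20,
) -> ContigSet:
    """Cleanup of the contigs assembled from one read cluster.

    (i) contigs are single-linkage clustered on their first ``prefix_len``
    bases (links at <= 2 edits or >= 96 % identity) and only the dominant
    cluster is kept, discarding contigs with atypical 5' starts; (ii)
    contigs shorter than 52 % of the maximum contig length are discarded;
    (iii) a contig contained in a longer (or equal-length, higher-abundance)
    contig - identity of its fragment excluding the last ``tail_exclude``
    bases above 98 % over >= 90 % of its length - is discarded. Idempotent.
    """
    log: list[dict] = []
    items = list(contigs)
    if not items:
        return ContigSet(contigs=[], cleanup_log=log)

    # (i) dominant 5'-prefix cluster
    prefixes = [c.seq[:prefix_len].upper() for c in items]
    n = len(items)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            max_edits = max(2, int(round((1 - prefix_identity) * min(len(prefixes[i]), len(prefixes[j])))))
            res = edlib.align(prefixes[i], prefixes[j], mode="NW", task="distance", k=max_edits)
            if res["editDistance"] >= 0:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    dominant = max(
        groups.values(),
        key=lambda members: (len(members), sum(items[i].abundance for i in members)),
    )
    dropped = n - len(dominant)
    if dropped:
        log.append({"rule": "atypical_prefix", "discarded": dropped})
    items = [items[i] for i in sorted(dominant)]

    # (ii) 52 % length rule
    max_len = max(len(c.seq) for c in items)
    short = [c for c in items if len(c.seq) < min_len_frac * max_len]
    if short:
        log.append({"rule": "short_contig", "discarded": len(short)})
    items = [c for c in items if len(c.seq) >= min_len_frac * max_len]

    # (iii) containment
    items.sort(key=lambda c: (len(c.seq), c.abundance, c.seq))
    kept: list[Contig] = []
    removed = 0
    for idx, c in enumerate(items):
        fragment = c.seq[:-tail_exclude] if len(c.seq) > tail_exclude else c.seq
        contained = False
        for other in items[idx + 1 :]:
            if len(other.seq) < len(c.seq):
                continue
            identity, frac_aln, _, _ = _infix_identity(fragment, other.seq)
            frac = frac_aln * len(fragment) / len(c.seq)
            if identity > containment_identity and frac >= containment_frac:
                contained = True
                break
        if contained:
            removed += 1
        else:
            kept.append(c)
    if removed:
        log.append({"rule": "contained_contig", "discarded": removed})
    kept.sort(key=lambda c: (-c.abundance, c.contig_id))
    return ContigSet(contigs=kept, cleanup_log=log)


def _tail_identity(qa: str, ta: str, tail: int) -> float:
    """Identity over the alignment columns covering the last ``tail`` query bases."""
    covered = 0
    matches = 0
    cols = 0
    for x, y in zip(reversed(qa), reversed(ta)):
        if covered >= tail:
            break
        cols += 1
        if x != "-":
            covered += 1
        if x == y and x != "-":
            matches += 1
    return matches / cols if cols else 0.0


def cleanup_global(
    contigs: Sequence[Contig],
    reference_catalog: Sequence[tuple[str, str, str]],
    min_aligned_frac: float = 0.90,
    max_start_offset: int = 5,
    max_ref_ns: int = 5,
    containment_identity: float = 0.96,
    containment_cover: float = 0.99,
    tail_lengths: tuple[int, int] = (15, 50),
    tail_rescue_identity: float = 0.80,
) -> ContigSet:
    """Catalog-based validation and final containment pass over all contigs.

    ``reference_catalog`` is a list of (ref_id, genus, sequence) records
    standing in for a labelled nucleotide database. A contig is kept when
    its best local alignment to a reference covers >= 90 % of its length,
    starts within the first five contig bases, and the matched reference
    region has fewer than five Ns; its 3' overhang beyond the matched region
    is trimmed and it inherits the reference genus. Within each source
    cluster only contigs of the typical genus (largest median contig length)
    survive. The final containment pass discards a contig contained at
    >= 96 % identity over 99 % of its length in a longer contig UNLESS its
    3'-terminal 15 bp or 50 bp identity against the container falls below
    80 % (rescuing diverging gene copies); equal-length duplicates keep the
    higher abundance.
    """
    if not reference_catalog:
        raise ValueError("empty reference catalog")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1

    log: list[dict] = []
    validated: list[Contig] = []
    n_dropped_aln = 0
    catalog = [(rid, genus, seq.upper()) for rid, genus, seq in reference_catalog]
    for contig in contigs:
        # cheap edlib pre-selection of the best reference, then one local
        # alignment for coordinates
        best_idx = min(
            range(len(catalog)),
            key=lambda i: edlib.align(
                contig.seq, catalog[i][2], mode="HW", task="distance"
            )["editDistance"],
        )
        _, genus, ref_seq = catalog[best_idx]
        ok = False
        try:
            top = aligner.align(contig.seq, ref_seq)[0]
        except IndexError:
            top = None
        if top is not None:
            q_start, q_end = int(top.aligned[0][0][0]), int(top.aligned[0][-1][1])
            t_start, t_end = int(top.aligned[1][0][0]), int(top.aligned[1][-1][1])
            aligned_len = q_end - q_start
            if (
                aligned_len >= min_aligned_frac * len(contig.seq)
                and q_start < max_start_offset
                and ref_seq[t_start:t_end].count("N") < max_ref_ns
            ):
                trimmed = contig.seq[:q_end]  # 3' overhang beyond the match
                validated.append(replace(contig, seq=trimmed, genus=genus))
                ok = True
        if not ok:
            n_dropped_aln += 1
    if n_dropped_aln:
        log.append({"rule": "no_catalog_match", "discarded": n_dropped_aln})

    # typical genus per source cluster
    kept: list[Contig] = []
    n_dropped_genus = 0
    by_cluster: dict[int, list[Contig]] = {}
    for c in validated:
        by_cluster.setdefault(c.source_cluster, []).append(c)
    for cluster_contigs in by_cluster.values():
        med_by_genus: dict[str, float] = {}
        for genus in {c.genus for c in cluster_contigs}:
            med_by_genus[genus] = median(
                len(c.seq) for c in cluster_contigs if c.genus == genus
            )
        typical = max(sorted(med_by_genus), key=lambda g: med_by_genus[g])
        for c in cluster_contigs:
            if c.genus == typical:
                kept.append(c)
            else:
                n_dropped_genus += 1
    if n_dropped_genus:
        log.append({"rule": "atypical_genus", "discarded": n_dropped_genus})

    # final containment pass with 3'-divergence rescue
    kept.sort(key=lambda c: (len(c.seq), c.abundance, c.seq))
    final: list[Contig] = []
    n_contained = 0
    for idx, c in enumerate(kept):
        contained = False
        for other in kept[idx + 1 :]:
            if len(other.seq) < len(c.seq):
                continue
            if len(other.seq) == len(c.seq) and other.abundance < c.abundance:
                continue
            identity, frac_aln, qa, ta = _infix_identity(c.seq, other.seq)
            if identity < containment_identity or frac_aln < containment_cover:
                continue
            rescued = any(
                _tail_identity(qa, ta, tail) < tail_rescue_identity
                for tail in tail_lengths
            )
            if not rescued:
                contained = True
                break
        if contained:
            n_contained += 1
        else:
            final.append(c)
    if n_contained:
        log.append({"rule": "contained_final", "discarded": n_contained})
    final.sort(key=lambda c: (-c.abundance, c.contig_id))
    return ContigSet(contigs=final, cleanup_log=log)


def call_copy_number(
    cleaned: ContigSet,
    grouping: Mapping[str, str] | str = "genus",
) -> dict[str, int]:
    """Copy number per group = count of retained contigs.

    ``grouping`` is either the string "genus" (group by assigned genus) or
    "cluster" (group by source cluster), or a mapping contig_id -> group.
    """
    counts: dict[str, int] = {}
    for c in cleaned.contigs:
        if isinstance(grouping, str):
            key = str(c.genus) if grouping == "genus" else str(c.source_cluster)
        else:
            key = grouping[c.contig_id]
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# FASTQ I/O (plain or gzip)


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Load paired FASTQ files (gzip accepted) into ReadPair objects."""
    import gzip
    from Bio import SeqIO

    def _open(path):
        path = str(path)
        return gzip.open(path, "rt") if path.endswith(".gz") else open(path)

    pairs = []
    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for rec1, rec2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            pairs.append(
                ReadPair(
                    read_id=rec1.id,
                    r1_seq=str(rec1.seq),
                    r2_seq=str(rec2.seq),
                    r1_qual="".join(
                        chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                    ),
                    r2_qual="".join(
                        chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                    ),
                )
            )
    return pairs
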