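"""Column-wise Shannon-entropy conservation profiles over MSAs.

Per-column entropy is S = -sum_i P_i log4(P_i), where P_i is the fraction of
non-gap residues in the column that are base i. The log base 4 normalises S
to [0, 1]: S = 1 means all four bases appear equally often (25 % each), S = 0
means a single base occupies the column. Columns are indexed on a designated
reference sequence; columns gapped in the reference are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"


@dataclass
class EntropyProfile:
    """Per-column entropy values and base counts.

    ``positions`` are reference-sequence offsets (0-based within the region;
    callers may label upstream offsets negative). ``entropy`` holds S values
    in [0, 1] (NaN where undefined); ``counts`` is an (n_columns, 4) matrix
    of A/C/G/T counts among non-gap residues.
    """

    positions: np.ndarray
    entropy: np.ndarray
    counts: np.ndarray
    region_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_BASES))
        df.insert(0, "position", self.positions)
        df.insert(1, "S", self.entropy)
        return df


def align(seqs: Sequence[str]) -> list[str]:
    """Progressive multiple alignment (guide tree + profile alignment).

    Substitution scores +2 match / -1 mismatch with affine gaps
    (open -10, extend -1). A single sequence is returned unchanged with a
    warning. Pre-aligned input (equal-length gapped strings) may be passed
    directly to :func:`column_entropy` instead.
    """
    seqs = [s.upper() for s in seqs]
    if len(seqs) == 0:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        warnings.warn("single sequence: returned unaligned", stacklevel=2)
        return list(seqs)

    import biotite.sequence as bseq
    import biotite.sequence.align as baln

    alphabet = bseq.NucleotideSequence.alphabet_unamb
    matrix = baln.SubstitutionMatrix(
        alphabet,
        alphabet,
        {(a, b): (2 if a == b else -1) for a in _BASES for b in _BASES},
    )
    records = [bseq.NucleotideSequence(s) for s in seqs]
    alignment, _order, _tree, _dists = baln.align_multiple(
        records, matrix, gap_penalty=(-10, -1)
    )
    # rows come back in input order
    return alignment.get_gapped_sequences()


def load_msa_fasta(path) -> list[str]:
    """Read a pre-aligned FASTA; all records must have equal length."""
    from Bio import SeqIO

    rows = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError("pre-aligned input has unequal sequence lengths")
    return rows


def column_entropy(
    msa: Sequence[str],
    reference_index: int = 0,
    region_label: str = "",
) -> EntropyProfile:
    """Entropy profile over reference-ungapped columns of an MSA.

    Gaps are excluded from the P_i denominator. A column whose non-reference
    rows are all gaps has no comparative information and is emitted as NaN.
    """
    if not msa:
        raise ValueError("empty MSA")
    lengths = {len(row) for row in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows must have equal length")
    if not 0 <= reference_index < len(msa):
        raise IndexError("reference_index out of range")

    arr = np.array([list(row.upper()) for row in msa])
    ref_row = arr[reference_index]
    keep = ref_row != "-"
    arr = arr[:, keep]

    n_cols = arr.shape[1]
    counts = np.zeros((n_cols, 4), dtype=int)
    for i, base in enumerate(_BASES):
        counts[:, i] = (arr == base).sum(axis=0)

    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        terms = np.where(p > 0, p * (np.log(p) / np.log(4.0)), 0.0)
    entropy = -terms.sum(axis=1)
    entropy[totals == 0] = np.nan

    # columns where every non-reference row is a gap: undefined
    others = np.delete(arr, reference_index, axis=0)
    if others.size:
        all_gap = (others == "-").all(axis=0)
        entropy[all_gap] = np.nan

    return EntropyProfile(
        positions=np.arange(n_cols),
        entropy=entropy,
        counts=counts,
        region_label=region_label,
    )


@dataclass(frozen=True)
class SamplingCaps:
    """Sub-sampling caps for per-rank entropy distributions."""

    members_per_rank: int = 20
    sub_members_per_member: int = 5
    strains_per_species: int = 2


def rank_entropy_distribution(
    table: pd.DataFrame,
    member_col: str,
    sub_member_col: str,
    caps: SamplingCaps = SamplingCaps(),
    seed: int = 0,
) -> dict[str, float]:
    """Mean column entropy per member of a taxonomic rank.

    ``table`` must hold one row per sequence with columns ``member_col``
    (e.g. genus), ``sub_member_col`` (e.g. species), ``strain`` and
    ``sequence``. Members, sub-members and strains-per-species are
    sub-sampled uniformly under ``caps`` with the given seed; members left
    with fewer than two sequences are skipped.
    """
    rng = np.random.default_rng(seed)
    members = sorted(table[member_col].unique())
    if len(members) > caps.members_per_rank:
        members = sorted(
            rng.choice(members, size=caps.members_per_rank, replace=False)
        )
    result: dict[str, float] = {}
    for member in members:
        sub = table[table[member_col] == member]
        sub_members = sorted(sub[sub_member_col].unique())
        if len(sub_members) > caps.sub_members_per_member:
            sub_members = sorted(
                rng.choice(sub_members, size=caps.sub_members_per_member, replace=False)
            )
        seqs: list[str] = []
        for sm in sub_members:
            block = sub[sub[sub_member_col] == sm]
            strains = sorted(block["strain"].unique())
            if len(strains) > caps.strains_per_species:
                strains = sorted(
                    rng.choice(strains, size=caps.strains_per_species, replace=False)
                )
            seqs.extend(block[block["strain"].isin(strains)]["sequence"].tolist())
        if len(seqs) < 2:
            continue
        profile = column_entropy(align(seqs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            result[member] = float(np.nanmean(profile.entropy))
    return result
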