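"""OTU clustering across identity thresholds and clustering-quality metrics.

Sequences are clustered by average-neighbour hierarchical clustering on
MSA-based pairwise distances (column mismatch fraction; internal gaps count
as differences, end-gaps are ignored), cut at distance 1 - threshold. A
clustering is scored against species labels with four metrics: richness
ratio min(S,O)/max(S,O), pair-level Matthews correlation, bijection (the
fraction of species whose sequences occupy exactly one cluster containing
nothing else) and normalized mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.cluster import normalized_mutual_info_score, pair_confusion_matrix

from .conservation import align


@dataclass
class Clustering:
    assignments: dict[str, int]  # sequence_id -> cluster_id
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


@dataclass
class ClusterMetricsReport:
    threshold: float
    S: int
    O: int
    richness_ratio: float
    mcc: float
    bijection: float
    nmi: float


def msa_distances(msa: Sequence[str]) -> np.ndarray:
    """Pairwise distance matrix from a multiple sequence alignment.

    Distance = mismatching columns / compared columns, where compared
    columns exclude each sequence's terminal gap runs (end-gaps) and
    columns where both sequences hold a gap.
    """
    n = len(msa)
    arr = np.array([list(s.upper()) for s in msa])
    is_gap = arr == "-"
    # per-row span of non-end-gap columns
    spans = []
    for i in range(n):
        non_gap = np.flatnonzero(~is_gap[i])
        if non_gap.size == 0:
            spans.append((0, -1))
        else:
            spans.append((non_gap[0], non_gap[-1]))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            if hi < lo:
                dist[i, j] = dist[j, i] = 1.0
                continue
            a = arr[i, lo : hi + 1]
            b = arr[j, lo : hi + 1]
            both_gap = (a == "-") & (b == "-")
            compared = (~both_gap).sum()
            if compared == 0:
                dist[i, j] = dist[j, i] = 1.0
                continue
            diffs = ((a != b) & ~both_gap).sum()
            dist[i, j] = dist[j, i] = diffs / compared
    return dist


def cluster_otus(
    seqs: Mapping[str, str] | Sequence[str],
    threshold: float,
    distances: np.ndarray | None = None,
    aligned: bool = False,
) -> Clustering:
    """Average-neighbour clustering cut at distance 1 - threshold.

    ``seqs`` maps sequence ids to sequences (or is a plain list, ids = row
    indices). Unaligned input is aligned first; pass ``aligned=True`` for
    gapped equal-length input, or supply ``distances`` directly.
    """
    if isinstance(seqs, Mapping):
        ids = list(seqs.keys())
        raw = list(seqs.values())
    else:
        ids = list(range(len(seqs)))
        raw = list(seqs)
    if not raw:
        return Clustering(assignments={}, threshold=threshold)
    if len(raw) == 1:
        return Clustering(assignments={ids[0]: 1}, threshold=threshold)
    if distances is None:
        msa = raw if aligned else align(raw)
        distances = msa_distances(msa)
    Z = linkage(squareform(distances, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    return Clustering(assignments=dict(zip(ids, map(int, labels))), threshold=threshold)


def richness_ratio(S: int, O: int) -> float:
    """min(S, O) / max(S, O); 1 when cluster count matches species count."""
    if S < 1 or O < 1:
        raise ValueError("S and O must be >= 1")
    return min(S, O) / max(S, O)


def pair_confusion_metrics(
    clustering: Clustering | Mapping[str, int],
    labels: Mapping[str, str],
) -> tuple[float, float, float]:
    """(MCC, NMI, bijection) of a clustering against species labels.

    MCC is computed over the pair-level confusion (TP = same-species pairs
    co-clustered, etc.); it is NaN when a marginal is empty (e.g. a single
    cluster and a single species). NMI is normalised by the arithmetic mean
    of the two entropies (natural logs).
    """
    assignments = clustering.assignments if isinstance(clustering, Clustering) else dict(clustering)
    ids = sorted(assignments)
    if set(ids) != set(labels):
        raise ValueError("labels must cover exactly the clustered sequences")
    pred = [assignments[i] for i in ids]
    true = [labels[i] for i in ids]

    cm = pair_confusion_matrix(true, pred).astype(float)
    tn, fp = cm[0]
    fn, tp = cm[1]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = float("nan") if denom == 0 else float((tp * tn - fp * fn) / np.sqrt(denom))

    nmi = float(normalized_mutual_info_score(true, pred, average_method="arithmetic"))

    species_ids: dict[str, set] = {}
    cluster_ids: dict[int, set] = {}
    for i in ids:
        species_ids.setdefault(labels[i], set()).add(i)
        cluster_ids.setdefault(assignments[i], set()).add(i)
    n_bijective = sum(
        1 for members in species_ids.values() if members in cluster_ids.values()
    )
    bijection = n_bijective / len(species_ids)
    return mcc, nmi, bijection


def optimal_threshold_sweep(
    table: pd.DataFrame,
    thresholds: Sequence[float],
    representative: bool = False,
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Metrics across clustering thresholds; per-metric argmax threshold.

    ``table`` holds one row per sequence with columns species, strain,
    sequence. In representative mode each species is reduced to a single
    uniformly chosen strain (seeded). Returns (argmax per metric, full
    metrics table); ties resolve to the lowest threshold.
    """
    df = table.reset_index(drop=True)
    if representative:
        rng = np.random.default_rng(seed)
        keep = []
        for species, block in df.groupby("species", sort=True):
            strains = sorted(block["strain"].unique())
            chosen = strains[rng.integers(len(strains))]
            keep.append(block[block["strain"] == chosen])
        df = pd.concat(keep).reset_index(drop=True)

    ids = [str(i) for i in df.index]
    labels = dict(zip(ids, df["species"]))
    msa = align(df["sequence"].tolist())
    distances = msa_distances(msa)
    S = df["species"].nunique()

    rows = []
    for t in sorted(thresholds):
        clustering = cluster_otus(dict(zip(ids, df["sequence"])), t, distances=distances)
        O = clustering.n_clusters
        mcc, nmi, bijection = pair_confusion_metrics(clustering, labels)
        rows.append(
            ClusterMetricsReport(
                threshold=t,
                S=S,
                O=O,
                richness_ratio=richness_ratio(S, O),
                mcc=mcc,
                bijection=bijection,
                nmi=nmi,
            )
        )
    frame = pd.DataFrame([vars(r) for r in rows])
    argmax: dict[str, float] = {}
    for metric in ("richness_ratio", "mcc", "bijection", "nmi"):
        col = frame[metric]
        if col.isna().all():
            argmax[metric] = float("nan")
        else:
            argmax[metric] = float(frame.loc[col.idxmax(), "threshold"])
    return argmax, frame
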