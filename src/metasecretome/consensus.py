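"""Replicate consensus, fraction bookkeeping and the clustering summary.

A protein is taken forward only when it is detected in every biological
replicate of its sample (in any fraction, by default). The fraction
bookkeeping then splits consensus proteins into biotin-labelled-only
(BF), supernatant-only (SNT) and shared, with 'present in a fraction'
meaning identified in that fraction in at least one replicate. The
stricter variant requiring per-fraction consensus is available as a
flag. The clustering summary z-scores each protein row of the molar
abundance matrix, clips to [-2, 2] for display, and clusters the run
columns by average-linkage agglomeration on Euclidean distances of the
unclipped scaled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .pipeline import ProteinIdentification


@dataclass
class ConsensusProtein:
    orf_id: str
    sample: str
    replicate_presence: dict[int, set[str]]  # replicate -> fractions seen
    consensus: bool
    fraction_class: str  # 'BF-only', 'SNT-only', 'both'


@dataclass
class VennSummary:
    n_total_consensus: int
    n_bf: int          # proteins appearing in BF (shared included)
    n_snt: int
    n_shared: int
    pct_shared: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_bf + self.n_snt - self.n_shared != self.n_total_consensus:
            raise ValueError("Venn identity violated: BF + SNT - shared != total")
        self.pct_shared = (
            100.0 * self.n_shared / self.n_total_consensus
            if self.n_total_consensus
            else 0.0
        )

    @property
    def n_bf_only(self) -> int:
        return self.n_bf - self.n_shared

    @property
    def n_snt_only(self) -> int:
        return self.n_snt - self.n_shared


def consensus_filter(
    identifications: list[ProteinIdentification],
    n_replicates: int = 3,
    per_fraction: bool = False,
) -> list[ConsensusProtein]:
    """One ConsensusProtein per (sample, orf_id).

    ``consensus`` is True when the protein was detected in all
    ``n_replicates`` replicates; with ``per_fraction`` the fraction class
    only counts fractions themselves seen in every replicate.
    """
    presence: dict[tuple[str, str], dict[int, set[str]]] = {}
    for ident in identifications:
        if not 1 <= ident.replicate <= n_replicates:
            raise ValueError(
                f"replicate {ident.replicate} outside 1..{n_replicates}"
            )
        key = (ident.sample, ident.orf_id)
        presence.setdefault(key, {}).setdefault(ident.replicate, set()).add(
            ident.fraction
        )
    out = []
    for (sample, orf_id), reps in sorted(presence.items()):
        consensus = len(reps) == n_replicates
        if per_fraction:
            fracs = {
                f
                for f in {f for s in reps.values() for f in s}
                if all(f in reps.get(r, set()) for r in range(1, n_replicates + 1))
            }
        else:
            fracs = {f for s in reps.values() for f in s}
        if fracs == {"BF"}:
            fclass = "BF-only"
        elif fracs == {"SNT"}:
            fclass = "SNT-only"
        elif fracs >= {"BF", "SNT"}:
            fclass = "both"
        else:  # consensus protein whose fractions all failed per-fraction rule
            fclass = "neither"
        out.append(
            ConsensusProtein(
                orf_id=orf_id,
                sample=sample,
                replicate_presence=reps,
                consensus=consensus,
                fraction_class=fclass,
            )
        )
    return out


def replicate_histogram(
    consensus: list[ConsensusProtein], n_replicates: int = 3
) -> pd.DataFrame:
    """Counts of proteins seen in k of n replicates, per sample and
    fraction (a protein counts toward each fraction it appears in)."""
    rows = []
    for cp in consensus:
        fractions = {f for s in cp.replicate_presence.values() for f in s}
        for fraction in sorted(fractions):
            k = sum(1 for fs in cp.replicate_presence.values() if fraction in fs)
            rows.append({"sample": cp.sample, "fraction": fraction, "k": k})
    if not rows:
        return pd.DataFrame(columns=["sample", "fraction", "k_of_n", "count"])
    df = pd.DataFrame(rows)
    hist = (
        df.groupby(["sample", "fraction", "k"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    hist["k_of_n"] = hist["k"].astype(str) + f"/{n_replicates}"
    return hist[["sample", "fraction", "k_of_n", "count"]]


def venn_summary(consensus: list[ConsensusProtein]) -> VennSummary:
    """BF/SNT overlap bookkeeping over consensus-passing proteins."""
    kept = [cp for cp in consensus if cp.consensus]
    n_bf = sum(1 for cp in kept if cp.fraction_class in ("BF-only", "both"))
    n_snt = sum(1 for cp in kept if cp.fraction_class in ("SNT-only", "both"))
    n_shared = sum(1 for cp in kept if cp.fraction_class == "both")
    return VennSummary(
        n_total_consensus=len(kept), n_bf=n_bf, n_snt=n_snt, n_shared=n_shared
    )


def scale_rows(mat: pd.DataFrame, clip: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row z-scores (mean 0, sd 1 with ddof=1; constant rows -> zeros).

    Returns (unclipped, clipped-for-display) frames; clipping to
    [-clip, clip] affects display only, never the clustering input.
    """
    values = mat.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    unclipped = pd.DataFrame(scaled, index=mat.index, columns=mat.columns)
    return unclipped, unclipped.clip(-clip, clip)


def cluster_heatmap_matrix(
    mat: pd.DataFrame, clip: float = 2.0
) -> tuple[pd.DataFrame, np.ndarray, list[str], str]:
    """Heatmap-style summary of a proteins x runs molar_pct matrix.

    Returns (display matrix clipped to [-clip, clip], column linkage,
    leaf-ordered column labels, Newick string of the column dendrogram).
    Columns are sorted by label before linkage so that distance ties
    break deterministically by column name.
    """
    if mat.shape[1] < 2:
        warnings.warn("fewer than 2 runs: scaling/clustering skipped")
        return mat.copy(), np.empty((0, 4)), list(mat.columns), ""
    mat = mat.reindex(sorted(mat.columns), axis=1)
    unclipped, display = scale_rows(mat, clip=clip)
    dist = pdist(unclipped.to_numpy().T, metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    labels = [mat.columns[i] for i in order]
    return display, link, labels, linkage_to_newick(link, list(mat.columns))


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick tree with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(link)

    def quote(label: str) -> str:
        if any(ch in label for ch in ":;,()[] '\t"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{quote(labels[node.id])}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def bootstrap_column_support(
    mat: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Plain bootstrap support for the column bipartitions of the
    dendrogram: fraction of row-resampled datasets whose average-linkage
    tree contains each observed cluster (as a set of column labels)."""
    if mat.shape[1] < 3:
        return {}
    mat = mat.reindex(sorted(mat.columns), axis=1)
    labels = list(mat.columns)

    def clusters_of(m: pd.DataFrame) -> set[frozenset[str]]:
        unclipped, _ = scale_rows(m)
        link = hierarchy.linkage(
            pdist(unclipped.to_numpy().T, metric="euclidean"), method="average"
        )
        tree = hierarchy.to_tree(link)
        out: set[frozenset[str]] = set()

        def leaves(node) -> list[int]:
            if node.is_leaf():
                return [node.id]
            return leaves(node.left) + leaves(node.right)

        def walk(node):
            if node.is_leaf():
                return
            out.add(frozenset(labels[i] for i in leaves(node)))
            walk(node.left)
            walk(node.right)

        walk(tree)
        return out

    observed = clusters_of(mat)
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in observed}
    for _ in range(n_boot):
        idx = rng.integers(0, mat.shape[0], size=mat.shape[0])
        boot = mat.iloc[idx]
        found = clusters_of(boot)
        for c in observed:
            if c in found:
                hits[c] += 1
    return {c: hits[c] / n_boot for c in observed}
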