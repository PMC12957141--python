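"""Niche-breadth statistics of a parasite's host assemblage.

Two statistics, computed on presence/absence host sets:

* Rao's quadratic diversity ``Q`` — the mean pairwise functional
  dissimilarity between hosts under equal weights 1/S, bounded by
  (S-1)/S for dissimilarities in [0, 1].

* Tree-slicing phylogenetic diversity ``D_P`` — the ultrametric host tree is
  cut at every node age into evolutionary periods; within each period the
  number of distinct ancestral lineages of the assemblage (lineage richness,
  D_k) is counted, and the period diversities are averaged weighted by
  period duration.  D_P is measured in effective lineages, with
  1 <= D_P <= S; two congeneric hosts in a deep tree score close to 1,
  hosts spanning the root score close to S.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from . import trees
from .gower import DissimilarityMatrix

__all__ = [
    "HostAssemblage",
    "NicheBreadthRecord",
    "rao_Q",
    "phylo_DP",
    "assemblage_table",
    "records_to_frame",
    "CONTINENTAL",
]

CONTINENTAL = "continental"


@dataclass(frozen=True)
class HostAssemblage:
    """A parasite's host set at one spatial scale (presence/absence)."""

    parasite: str
    hosts: frozenset
    scale: str = CONTINENTAL

    def __post_init__(self) -> None:
        if not self.hosts:
            raise ValueError(f"assemblage for {self.parasite!r} has no hosts")


@dataclass(frozen=True)
class NicheBreadthRecord:
    """(parasite, scale, S, D_P, Q) — the analysis' central quantity."""

    parasite: str
    scale: str
    s: int
    d_p: float
    q: float


def rao_Q(a: HostAssemblage, d: DissimilarityMatrix) -> float:
    """Rao's quadratic diversity: Q = (1/S^2) sum_ij d_ij over the S hosts."""
    hosts = sorted(a.hosts)
    sub = d.submatrix(hosts)  # raises on missing host
    s = len(hosts)
    return float(sub.sum()) / (s * s)


def phylo_DP(
    a: HostAssemblage,
    t: dendropy.Tree,
    weighting: str = "duration",
    rtol: float = trees.ULTRAMETRIC_RTOL,
) -> float:
    """Tree-slicing phylogenetic diversity of a host assemblage.

    The tree's distinct node ages 0 = t_0 < ... < t_m = T delimit the
    evolutionary periods.  D_k is the number of distinct lineages ancestral
    to the assemblage crossing the midpoint of period k (richness index).
    With ``weighting="duration"`` (default) the periods are averaged with
    weights (t_k - t_{k-1})/T; ``weighting="equal"`` takes the plain mean.
    """
    if weighting not in ("duration", "equal"):
        raise ValueError("weighting must be 'duration' or 'equal'")
    tips = set(trees.tip_labels(t))
    unknown = set(a.hosts) - tips
    if unknown:
        raise KeyError(f"hosts absent from tree: {sorted(unknown)}")
    ages = trees.node_ages(t, rtol=rtol)  # rejects non-ultrametric trees
    height = max(ages.values())
    if height <= 0:
        raise ValueError("tree has zero height; D_P is undefined")

    # distinct node ages, collapsing numerically-duplicate ages
    cuts: list[float] = []
    for v in sorted(ages.values()):
        if not cuts or v - cuts[-1] > rtol * height:
            cuts.append(v)
    cuts[0], cuts[-1] = 0.0, height

    # ancestral lineages of the assemblage: each surviving edge spans
    # [age(child), age(parent)]
    label_to_leaf = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    edges = set()
    for h in a.hosts:
        node = label_to_leaf[h]
        while node.parent_node is not None:
            edges.add(node)
            node = node.parent_node
    spans = [(ages[n], ages[n.parent_node]) for n in edges]

    total = 0.0
    weight_sum = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = (lo + hi) / 2.0
        d_k = sum(1 for a0, a1 in spans if a0 <= mid < a1)
        w = (hi - lo) if weighting == "duration" else 1.0
        total += w * d_k
        weight_sum += w
    return total / weight_sum


def assemblage_table(
    inc,
    t: dendropy.Tree,
    d: DissimilarityMatrix,
    weighting: str = "duration",
) -> list[NicheBreadthRecord]:
    """Niche breadth of every parasite at every scale of an incidence set.

    ``inc`` must expose ``regional_matrices`` (region -> {parasite: host set})
    and ``continental_matrix`` ({parasite: host set}); see the pipeline
    module.  For each scale, D_P is computed on the host tree pruned to that
    scale's host pool (the union of hosts present at the scale) with the
    original root retained, so the full tree's depth context is kept.
    """
    records: list[NicheBreadthRecord] = []
    scales = [(region, mat) for region, mat in inc.regional_matrices.items()]
    scales.append((CONTINENTAL, inc.continental_matrix))
    for scale, mat in scales:
        if not mat:
            continue
        pool = sorted(set().union(*mat.values()))
        pool_tree = trees.prune(t, pool)
        for parasite in sorted(mat):
            a = HostAssemblage(parasite=parasite, hosts=frozenset(mat[parasite]), scale=scale)
            records.append(
                NicheBreadthRecord(
                    parasite=parasite,
                    scale=scale,
                    s=len(a.hosts),
                    d_p=phylo_DP(a, pool_tree, weighting=weighting),
                    q=rao_Q(a, d),
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate niche-breadth records (columns parasite, scale, S, D_P, Q)."""
    return pd.DataFrame(
        [
            {"parasite": r.parasite, "scale": r.scale, "S": r.s, "D_P": r.d_p, "Q": r.q}
            for r in records
        ]
    )
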