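"""Clade extraction by complete-linkage clustering of Pearson distances.

Proteins sharing a temporal/temperature abundance pattern are grouped by
agglomerative clustering with the complete (maximum) linkage rule on the
correlation distance d(p, q) = 1 - r(p, q), r the Pearson correlation of the
two protein rows across biological samples (d in [0, 2]). Cutting the
dendrogram at a fixed height yields clades in which every within-clade
pairwise distance is at most the cut height. Each clade is summarized by its
mean autoscaled abundance per sample with a t-based 95% confidence interval.

Pearson distance is invariant to per-row affine rescaling, so clustering the
autoscaled matrix (as the heatmaps display) equals clustering the raw rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .io import AbundanceMatrix, ProtascaError, SampleDesign

#: clade color aliases used in the original study's figures, by analysis
CLADE_COLOR_ALIASES = {
    "time": ("light blue", "purple", "green", "gray", "black"),
    "temperature": ("orange", "dark teal"),
    "pca_temperature": ("pale yellow", "salmon", "pale purple"),
}


@dataclass
class CladeAssignment:
    """Complete-linkage tree plus a flat cut into clades.

    ``labels`` maps protein id -> clade label; labels are integers assigned
    in decreasing clade-size order (1 = largest). ``linkage`` is the scipy
    linkage matrix over ``protein_ids``.
    """

    linkage: np.ndarray
    protein_ids: list[str]
    cut_height: float | None
    labels: pd.Series
    n_clades: int

    def members(self, clade: int) -> list[str]:
        return list(self.labels.index[self.labels == clade])

    @property
    def clade_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_newick(self) -> str:
        """Dendrogram as a Newick string, branch lengths from merge heights."""
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.protein_ids[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                ln = (node.dist - child.dist) if not child.is_leaf() else node.dist
                parts.append(f"{rec(child)}:{ln:.10g}")
            return "(" + ",".join(parts) + ")"

        return rec(tree) + ";"


def pearson_distance_matrix(m: AbundanceMatrix,
                            drop_zero_variance: bool = False) -> pd.DataFrame:
    """Pairwise 1 - Pearson(r) distances between protein rows.

    Rows with zero variance have undefined correlation; they raise an error
    naming the proteins unless ``drop_zero_variance`` is set, in which case
    they are dropped with a warning.
    """
    if m.values.shape[1] < 2:
        raise ProtascaError("Pearson distance needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    ids = list(m.values.index)
    if flat.size:
        names = [ids[i] for i in flat]
        if not drop_zero_variance:
            raise ProtascaError(f"zero-variance protein rows: {names}")
        warnings.warn(f"dropping {len(names)} zero-variance rows", stacklevel=2)
        keep = np.setdiff1d(np.arange(len(ids)), flat)
        vals = vals[keep]
        ids = [ids[i] for i in keep]
    r = np.corrcoef(vals)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=ids, columns=ids)


def hierarchical_clades(dist: pd.DataFrame,
                        cut_height: float | None = None,
                        n_clades: int | None = None) -> CladeAssignment:
    """Complete-linkage agglomeration cut into clades.

    Exactly one of ``cut_height`` (remove merges above this height; every
    within-clade pairwise distance is then <= cut_height) or ``n_clades``
    (cut into a requested number of clades) must be given. Clade labels are
    renumbered 1..k in decreasing clade-size order, ties broken by first
    protein appearance, so output is deterministic.
    """
    if (cut_height is None) == (n_clades is None):
        raise ProtascaError("give exactly one of cut_height or n_clades")
    if cut_height is not None and cut_height <= 0:
        raise ProtascaError("cut_height must be positive")
    ids = list(dist.index)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method="complete")
    if cut_height is not None:
        raw = sch.fcluster(Z, t=cut_height, criterion="distance")
    else:
        raw = sch.fcluster(Z, t=n_clades, criterion="maxclust")
    labels = _relabel_by_size(raw)
    series = pd.Series(labels, index=pd.Index(ids, name="protein_id"),
                       name="clade")
    return CladeAssignment(linkage=Z, protein_ids=ids, cut_height=cut_height,
                           labels=series, n_clades=int(labels.max()))


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.asarray([remap[v] for v in raw])


def clade_profiles(m: AbundanceMatrix, clades: CladeAssignment,
                   design: SampleDesign,
                   confidence: float = 0.95) -> pd.DataFrame:
    """Per-clade mean abundance profile with t-based confidence intervals.

    For each clade and biological sample: the mean over member proteins of
    the (autoscaled) abundance, with CI = mean +/- t(1-(1-conf)/2, n-1) *
    sd / sqrt(n) over member proteins. Single-protein clades get zero-width
    intervals flagged ``degenerate``.
    """
    missing = [p for p in clades.labels.index if p not in m.values.index]
    if missing:
        raise ProtascaError(f"clustered proteins absent from matrix: {missing}")
    rows = []
    for clade in sorted(clades.labels.unique()):
        members = clades.members(clade)
        if not members:
            raise ProtascaError(f"empty clade {clade}")
        sub = m.values.loc[members]
        mean = sub.mean(axis=0)
        n = len(members)
        if n > 1:
            sd = sub.std(axis=0, ddof=1)
            half = t_dist.ppf(1 - (1 - confidence) / 2, n - 1) * sd / np.sqrt(n)
        else:
            half = pd.Series(0.0, index=mean.index)
        for sample in m.values.columns:
            drow = design.table.loc[sample] if sample in design.table.index else None
            rows.append({
                "clade": clade,
                "sample_id": sample,
                "time_dpf": int(drow["time_dpf"]) if drow is not None else None,
                "temperature_c": float(drow["temperature_c"]) if drow is not None else None,
                "mean": float(mean[sample]),
                "ci_lower": float(mean[sample] - half[sample]),
                "ci_upper": float(mean[sample] + half[sample]),
                "n_proteins": n,
                "degenerate": n == 1,
            })
    return pd.DataFrame(rows)
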