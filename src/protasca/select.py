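"""Loadings-based protein selection.

Proteins driving a principal or simultaneous component are picked from the
component's loadings, either with explicit upper/lower thresholds or with an
automated elbow rule on the magnitude-ranked loadings curve. Selections from
several components are combined by union.

``PAPER_PRESETS`` ships the threshold sets used in the oyster metamorphosis
study this framework reproduces, for users re-running its published matrices;
the elbow finder is the default for new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import PcaResult
from .io import ProtascaError

#: named threshold presets (component -> (upper, lower)) from the original
#: study: preliminary PCA, ASCA time effect (PC1+PC2), ASCA temperature (PC1)
PAPER_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "pca_temperature": {"PC1": (0.0236, -0.02355), "PC2": (0.0245, -0.0262)},
    "asca_time": {"PC1": (0.035, -0.035), "PC2": (0.035, -0.035)},
    "asca_temperature": {"PC1": (0.03, -0.025)},
}


@dataclass
class LoadingsSelection:
    """One component's ranked loadings, thresholds, and selected protein set."""

    component_id: str
    ranked: pd.DataFrame  # columns: protein_id, loading; sorted by |loading| desc
    upper_threshold: float
    lower_threshold: float
    selected: frozenset[str]
    method: str  # "manual" or "elbow"


def rank_loadings(pca: PcaResult | pd.DataFrame,
                  components: list[str]) -> dict[str, pd.DataFrame]:
    """Rank every protein by decreasing loading magnitude, per component.

    Ties in magnitude are broken by lexicographic protein id so the ranking
    is a deterministic permutation of all proteins.
    """
    loadings = pca.loadings if isinstance(pca, PcaResult) else pca
    out: dict[str, pd.DataFrame] = {}
    for comp in components:
        if comp not in loadings.columns:
            raise ProtascaError(f"unknown component {comp!r}; "
                                f"have {list(loadings.columns)}")
        df = pd.DataFrame({"protein_id": loadings.index.astype(str),
                           "loading": loadings[comp].to_numpy()})
        df["_mag"] = df["loading"].abs()
        df = (df.sort_values(["_mag", "protein_id"],
                             ascending=[False, True], kind="mergesort")
                .drop(columns="_mag").reset_index(drop=True))
        out[comp] = df
    return out


def select_by_threshold(ranked: pd.DataFrame, upper: float, lower: float,
                        component_id: str = "PC1",
                        method: str = "manual") -> LoadingsSelection:
    """Select proteins with loading >= upper or <= lower."""
    if lower >= upper:
        raise ProtascaError(f"lower threshold {lower} must be < upper {upper}")
    mask = (ranked["loading"] >= upper) | (ranked["loading"] <= lower)
    return LoadingsSelection(
        component_id=component_id, ranked=ranked,
        upper_threshold=upper, lower_threshold=lower,
        selected=frozenset(ranked.loc[mask, "protein_id"]), method=method)


def find_elbow(ranked: pd.DataFrame, rel_tol: float = 1e-9) -> tuple[int, float]:
    """Elbow of the magnitude-ranked loadings curve.

    Automated surrogate for placing a threshold "at the point of diminishing
    returns" by eye: the elbow is the index maximizing the perpendicular
    distance between the sorted ``|loading|`` curve and the chord joining its
    first and last points. Returns ``(index, |loading| at index)``. A curve
    indistinguishable from its chord (relative deviation below ``rel_tol``)
    has no elbow and raises.
    """
    y = ranked["loading"].abs().to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ProtascaError("elbow needs at least 3 ranked values")
    x = np.arange(n, dtype=float)
    # uniform x spacing: argmax of perpendicular distance == argmax of
    # vertical deviation from the chord
    chord = y[0] + (y[-1] - y[0]) * x / (n - 1)
    dev = np.abs(y - chord)
    scale = max(abs(y[0] - y[-1]), np.abs(y).max(), 1e-300)
    if dev.max() <= rel_tol * scale:
        raise ProtascaError("no elbow: loadings curve is indistinguishable "
                            "from a straight line")
    idx = int(dev.argmax())
    return idx, float(y[idx])


def select_by_elbow(ranked: pd.DataFrame,
                    component_id: str = "PC1") -> LoadingsSelection:
    """Threshold at the elbow magnitude; selects |loading| >= elbow value."""
    _, thr = find_elbow(ranked)
    return select_by_threshold(ranked, upper=thr, lower=-thr,
                               component_id=component_id, method="elbow")


def union_selections(selections: list[LoadingsSelection]) -> frozenset[str]:
    """Union of selected proteins across components."""
    out: frozenset[str] = frozenset()
    for sel in selections:
        out = out | sel.selected
    return out


def select_components_by_variance(pca: PcaResult,
                                  min_cumulative: float = 0.9,
                                  max_components: int | None = None) -> list[str]:
    """Smallest leading component set whose cumulative explained variance
    reaches ``min_cumulative`` (components with zero variance never enter)."""
    frac = np.asarray(pca.explained_variance_fraction, dtype=float)
    total = frac.sum()
    if total <= 0:
        raise ProtascaError("no variance to explain")
    cum = np.cumsum(frac) / total
    k = int(np.searchsorted(cum, min_cumulative) + 1)
    k = min(k, int((frac > 0).sum()))
    if max_components is not None:
        k = min(k, max_components)
    return [f"PC{i + 1}" for i in range(k)]
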