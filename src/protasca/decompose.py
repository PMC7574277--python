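"""PCA and ANOVA-simultaneous component analysis (ASCA) with permutation tests.

ASCA partitions a column-centered samples x proteins matrix ``Xc`` into
additive effect matrices, one per experimental factor:

    Xc = X_time + X_temperature + X_interaction + E

where row *i* of ``X_time`` is the mean of the ``Xc`` rows sharing sample
*i*'s time level (temperature analogously), the interaction row is the
(time, temperature) cell mean minus both main effects, and ``E`` is what
remains. Each factor's contribution is reported as
``100 * ||X_f||_F^2 / ||Xc||_F^2``; in a balanced design the effect matrices
are mutually orthogonal and these percentages plus the residual share sum to
100 (Pythagorean identity). Each effect matrix is then summarized by a
simultaneous component analysis — a PCA of the (already centered) effect
matrix — yielding per-factor scores and loadings.

Significance of an effect is assessed by permutation: the factor's level
labels are reassigned uniformly at random across samples, the factor's sum
of squares recomputed, and the p-value taken as the fraction of permuted
sums of squares at least as large as the observed one (with the +1
correction by default, so p is never exactly zero).

With one observation per (time, temperature) cell the design is saturated:
the interaction is confounded with residual error. It is still reported as
"interaction" for comparability, and a note is logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ProtascaError, RunRecord, SampleDesign

FACTORS = ("time", "temperature", "interaction")


@dataclass
class PcaResult:
    """Scores (samples x components), loadings (variables x components,
    unit-norm columns), and explained-variance fractions.

    The sign of each component is fixed so that the largest-magnitude entry
    of its loadings column is positive, making loadings thresholds
    reproducible across linear-algebra backends.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class PermutationSpec:
    """Permutation-test configuration: count, seed, p-value rule."""

    n_permutations: int = 10_000
    seed: int = 0
    p_value_rule: str = "plus_one"  # or "raw"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ProtascaError("n_permutations must be >= 1")
        if self.p_value_rule not in ("plus_one", "raw"):
            raise ProtascaError("p_value_rule must be 'plus_one' or 'raw'")


@dataclass
class AscaResult:
    """Per-factor effect matrices, variance shares, SCA components, p-values."""

    effects: dict[str, pd.DataFrame]
    residual: pd.DataFrame
    percent_variation: dict[str, float]
    residual_percent: float
    sca: dict[str, PcaResult]
    permutation_p: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    factor_labels: dict[str, pd.Series] = field(default_factory=dict)
    centered: pd.DataFrame | None = None
    balanced: bool = True
    saturated: bool = False


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def run_pca(m: AbundanceMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples over protein variables via SVD of the centered matrix.

    Columns (proteins) are mean-centered but not scaled to unit variance.
    Scores reconstruct the centered matrix: ``scores @ loadings.T == Xc``.
    """
    X = m.values.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 2:
        raise ProtascaError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    return _pca_of(Xc, sample_ids=m.sample_ids, var_ids=m.protein_ids,
                   n_components=n_components)


def _pca_of(Xc: np.ndarray, sample_ids, var_ids,
            n_components: int | None = None) -> PcaResult:
    """SVD-based PCA of an already-centered matrix (used for SCA too)."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(Xc.shape)
    if n_components is not None:
        k = min(k, n_components)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    total = (s ** 2).sum()
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=list(sample_ids), columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=list(var_ids), columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=explained)


# ---------------------------------------------------------------------------
# ASCA
# ---------------------------------------------------------------------------


def _group_mean_rows(Xc: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row i of the result is the mean of Xc rows sharing labels[i]."""
    out = np.empty_like(Xc)
    for lev in np.unique(labels):
        mask = labels == lev
        out[mask] = Xc[mask].mean(axis=0)
    return out


def decompose_asca(
    m: AbundanceMatrix,
    design: SampleDesign,
    include_interaction: bool = True,
    run_record: RunRecord | None = None,
) -> AscaResult:
    """Partition protein abundance variation into time, temperature and
    interaction effect matrices and summarize each by SCA.

    Expects the log2-scale replicate-averaged matrix with one column per
    design row. Unbalanced designs are computed with a warning that effect
    orthogonality is not guaranteed.
    """
    order = design.sample_ids
    missing = [s for s in order if s not in m.values.columns]
    if missing:
        raise ProtascaError(f"design samples absent from matrix: {missing}")
    X = m.values[order].to_numpy(dtype=float).T  # samples x proteins
    labels = {
        "time": design.table["time_dpf"].to_numpy(),
        "temperature": design.table["temperature_c"].to_numpy(),
    }
    for fac, lab in labels.items():
        if np.unique(lab).size < 2:
            raise ProtascaError(f"factor {fac!r} has a single level")

    balanced = design.is_balanced
    if not balanced:
        warnings.warn("unbalanced design: effect matrices are not guaranteed "
                      "orthogonal; percent variation shares may exceed 100",
                      stacklevel=2)
        if run_record is not None:
            run_record.log("asca: unbalanced design warning")

    Xc = X - X.mean(axis=0, keepdims=True)
    effects: dict[str, np.ndarray] = {
        "time": _group_mean_rows(Xc, labels["time"]),
        "temperature": _group_mean_rows(Xc, labels["temperature"]),
    }
    cell = [f"{t}/{g}" for t, g in zip(labels["time"], labels["temperature"])]
    cell = np.asarray(cell)
    if include_interaction:
        cell_mean = _group_mean_rows(Xc, cell)
        effects["interaction"] = cell_mean - effects["time"] - effects["temperature"]
    residual = Xc - sum(effects.values())

    saturated = len(np.unique(cell)) == len(order)
    if saturated and include_interaction and run_record is not None:
        run_record.log("asca: saturated design; the interaction term is "
                       "confounded with residual noise")

    total_ss = float((Xc ** 2).sum())
    if total_ss == 0:
        raise ProtascaError("matrix has no variation across samples")
    percent = {f: 100.0 * float((E ** 2).sum()) / total_ss
               for f, E in effects.items()}
    residual_percent = 100.0 * float((residual ** 2).sum()) / total_ss

    sca = {
        f: _pca_of(E, sample_ids=order, var_ids=m.protein_ids)
        for f, E in effects.items()
    }
    idx = pd.Index(order, name="sample_id")
    return AscaResult(
        effects={f: pd.DataFrame(E, index=idx, columns=m.protein_ids)
                 for f, E in effects.items()},
        residual=pd.DataFrame(residual, index=idx, columns=m.protein_ids),
        percent_variation=percent,
        residual_percent=residual_percent,
        sca=sca,
        factor_labels={f: pd.Series(lab, index=idx)
                       for f, lab in labels.items()},
        centered=pd.DataFrame(Xc, index=idx, columns=m.protein_ids),
        balanced=balanced,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------


def _main_effect_ssq(Xc: np.ndarray, labels: np.ndarray) -> float:
    """Sum of squares of the main-effect matrix for one factor."""
    ssq = 0.0
    for lev in np.unique(labels):
        mask = labels == lev
        gm = Xc[mask].mean(axis=0)
        ssq += mask.sum() * float(gm @ gm)
    return ssq


def _effect_operator(labels: np.ndarray) -> np.ndarray:
    """n x n matrix A with (A @ X) assigning each row its group mean."""
    n = labels.shape[0]
    A = np.zeros((n, n))
    for lev in np.unique(labels):
        mask = labels == lev
        A[np.ix_(mask, mask)] = 1.0 / mask.sum()
    return A


def permutation_test(
    m: AbundanceMatrix,
    design: SampleDesign,
    factor: str,
    spec: PermutationSpec = PermutationSpec(),
) -> float:
    """Permutation p-value for one ASCA factor's sum of squares.

    The factor's level labels are reassigned uniformly at random across
    samples (equivalently, sample rows are permuted against the fixed label
    vector, so the other factor's labels stay attached to samples) and the
    factor's effect sum of squares is recomputed for each permutation. For
    the interaction term the full design is reshuffled and the interaction
    effect (cell mean minus both main effects) recomputed. Under the
    ``plus_one`` rule p = (1 + #{SSQ_perm >= SSQ_obs}) / (1 + N).
    Deterministic given ``spec.seed``.
    """
    if factor not in FACTORS:
        raise ProtascaError(f"unknown factor {factor!r}")
    order = design.sample_ids
    X = m.values[order].to_numpy(dtype=float).T
    Xc = X - X.mean(axis=0, keepdims=True)
    n = Xc.shape[0]

    if factor == "interaction":
        t = design.table["time_dpf"].to_numpy()
        g = design.table["temperature_c"].to_numpy()
        cell = np.asarray([f"{a}/{b}" for a, b in zip(t, g)])
        A = _effect_operator(cell) - _effect_operator(t) - _effect_operator(g)
        A += np.full((n, n), 1.0 / n)  # grand mean (zero on centered data)
        observed = float(((A @ Xc) ** 2).sum())
        op = A
    else:
        lab = design.factor_labels(factor).to_numpy()
        observed = _main_effect_ssq(Xc, lab)
        op = _effect_operator(lab)

    rng = np.random.default_rng(spec.seed)
    perms = np.stack([rng.permutation(n) for _ in range(spec.n_permutations)])
    exceed = 0
    chunk = max(1, int(5e6) // max(1, Xc.size))
    for start in range(0, spec.n_permutations, chunk):
        P = perms[start:start + chunk]
        Y = Xc[P]                                   # (c, n, p)
        E = np.einsum("ij,cjp->cip", op, Y)
        ssq = np.einsum("cip,cip->c", E, E)
        exceed += int((ssq >= observed).sum())
    if spec.p_value_rule == "plus_one":
        return (1 + exceed) / (1 + spec.n_permutations)
    return exceed / spec.n_permutations


def run_permutation_tests(
    m: AbundanceMatrix,
    design: SampleDesign,
    asca: AscaResult,
    spec: PermutationSpec = PermutationSpec(),
) -> AscaResult:
    """Fill ``asca.permutation_p`` for every factor present in the result."""
    for i, factor in enumerate(asca.effects):
        sub = PermutationSpec(n_permutations=spec.n_permutations,
                              seed=spec.seed + i, p_value_rule=spec.p_value_rule)
        asca.permutation_p[factor] = permutation_test(m, design, factor, sub)
    asca.n_permutations = spec.n_permutations
    return asca


def summarize_effects(asca: AscaResult) -> pd.DataFrame:
    """Factor / percent-variation / permutation-p table.

    Percentages are rounded to 2 decimals and p-values to 4, the convention
    used when reporting an ASCA variance partition.
    """
    rows = []
    for factor in asca.effects:
        rows.append({
            "factor": factor,
            "percent_variation": round(asca.percent_variation[factor], 2),
            "p_value": (round(asca.permutation_p[factor], 4)
                        if factor in asca.permutation_p else None),
        })
    return pd.DataFrame(rows)
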