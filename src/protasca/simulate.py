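"""Synthetic spectral-count datasets with planted abundance archetypes.

The generator emulates a 6-timepoint (21-31 days post-fertilization, every
2 days) x 2-temperature (23 / 29 degrees C) larval development design with
technical duplicates per biological sample, on the scale of a shotgun
proteomics experiment (~2000 proteins, ~95,000 acquired spectra per sample).

Each protein gets a log2 baseline abundance; planted proteins additionally
follow one of seven archetype templates over the 12 design cells:

* five temporal shapes — an acute drop after the first time point, a gradual
  decrease, an up-down-up oscillation with extrema at 25 and 29 dpf, its
  mirror image, and a gradual increase — identical at both temperatures;
* two temperature shapes — a constant offset up or down at 29 relative to
  23 degrees C, flat in time.

Templates are mean-zero and unit-norm over the 12 cells, scaled by an
amplitude in log2 units. Independent Gaussian noise is added per technical
replicate, and spectral counts are drawn per sample from a multinomial with
probabilities proportional to ``2**log2_abundance * length``, tying the
counts to the NSAF definition so NSAF quantification approximately inverts
the generator. Ground-truth labels and recovery metrics (precision, recall,
adjusted Rand index) make every downstream stage testable without data
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import CladeAssignment
from .io import AbundanceMatrix, ProtascaError, SampleDesign, SpectralCountTable
from .select import LoadingsSelection

TIME_POINTS = (21, 23, 25, 27, 29, 31)
TEMPERATURES = (23.0, 29.0)

TIME_ARCHETYPES = ("acute_decrease", "gradual_decrease", "osc_up_down_up",
                   "osc_down_up_down", "gradual_increase")
TEMP_ARCHETYPES = ("temp_up", "temp_down")
ARCHETYPES = TIME_ARCHETYPES + TEMP_ARCHETYPES + ("null",)


@dataclass(frozen=True)
class ArchetypeSpec:
    """How many proteins to plant with one archetype, at what amplitude.

    ``amplitude`` is in log2 units applied to the unit-norm template; the
    default 2.0 gives peak-to-trough fold changes around 4x, typical of
    strongly developmentally regulated proteins.
    """

    name: str
    n_proteins: int
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ProtascaError(f"unknown archetype {self.name!r}")
        if self.amplitude < 0:
            raise ProtascaError("amplitude must be >= 0")
        if self.n_proteins < 0:
            raise ProtascaError("n_proteins must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset."""

    labels: pd.Series            # protein_id -> archetype name
    params: dict = field(default_factory=dict)
    seed: int = 0
    latent_log2: pd.DataFrame | None = None   # noiseless log2 abundance per cell
    #: log2 abundance per technical replicate (latent + noise), the surface
    #: the multinomial counts were drawn from
    log2_replicates: pd.DataFrame | None = None

    @property
    def planted(self) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels != "null"])

    def planted_with(self, names: tuple[str, ...]) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels.isin(names)])


def default_specs(n_per_time: int = 100, n_per_temp: int = 50,
                  amplitude: float = 2.0) -> list[ArchetypeSpec]:
    """Default planted mixture: 100 proteins per temporal archetype and 50
    per temperature archetype (500 + 100 planted)."""
    return ([ArchetypeSpec(a, n_per_time, amplitude) for a in TIME_ARCHETYPES]
            + [ArchetypeSpec(a, n_per_temp, amplitude) for a in TEMP_ARCHETYPES])


def archetype_templates(
    time_points: tuple[int, ...] = TIME_POINTS,
    temperatures: tuple[float, ...] = TEMPERATURES,
) -> dict[str, np.ndarray]:
    """Mean-zero, unit-norm archetype templates over the design cells.

    Cells are ordered by (time, temperature); each template is a vector of
    length ``len(time_points) * len(temperatures)``. The ``null`` template is
    all zeros (and not normalized).
    """
    nt, ng = len(time_points), len(temperatures)
    if nt != 6 or ng != 2:
        raise ProtascaError("templates are defined on 6 time points x 2 temperatures")

    def per_time(shape: np.ndarray) -> np.ndarray:
        return np.repeat(shape, ng)  # same value at both temperatures

    acute = per_time(np.array([1.0, 0, 0, 0, 0, 0]))
    gradual_dec = per_time(np.linspace(1.0, -1.0, nt))
    # one full excursion: rises to a maximum at 25 dpf, falls to a minimum
    # at 29 dpf, rises again at 31 dpf
    osc = per_time(np.array([-1.0, 0.0, 1.0, 0.0, -1.0, 0.0]))
    temp_sign = np.tile([-1.0, 1.0], nt)  # -1 at the cooler, +1 at the warmer

    raw = {
        "acute_decrease": acute,
        "gradual_decrease": gradual_dec,
        "gradual_increase": -gradual_dec,
        "osc_up_down_up": osc,
        "osc_down_up_down": -osc,
        "temp_up": temp_sign,
        "temp_down": -temp_sign,
    }
    out = {}
    for name, v in raw.items():
        v = v - v.mean()
        out[name] = v / np.linalg.norm(v)
    out["null"] = np.zeros(nt * ng)
    return out


def generate_dataset(
    specs: list[ArchetypeSpec] | None = None,
    noise_sd: float = 0.25,
    n_null: int = 1400,
    total_spectra: int = 95_000,
    seed: int = 0,
    baseline_log2_mean: float = -12.0,
    baseline_log2_sd: float = 2.0,
    n_replicates: int = 2,
) -> tuple[SpectralCountTable, SampleDesign, SyntheticTruth]:
    """Generate counts, design and ground truth for the planted design.

    Per protein: log2 abundance = baseline (normal, default mean -12 sd 2,
    i.e. log-normal relative abundance spanning several orders of magnitude)
    + amplitude x template over the 12 cells. Per technical replicate an
    independent N(0, noise_sd) is added per cell. Protein lengths are
    log-normal around ~350 residues. Counts per sample are one multinomial
    draw of ``total_spectra`` spectra with probabilities proportional to
    ``2**log2_value * length``. Everything is driven by ``seed``: the same
    call is bit-identical.
    """
    if noise_sd < 0:
        raise ProtascaError("noise_sd must be >= 0")
    if total_spectra <= 0:
        raise ProtascaError("total_spectra must be positive")
    if specs is None:
        specs = default_specs()
    templates = archetype_templates()
    rng = np.random.default_rng(seed)

    labels: list[str] = []
    amplitudes: list[float] = []
    for spec in specs:
        labels.extend([spec.name] * spec.n_proteins)
        amplitudes.extend([spec.amplitude] * spec.n_proteins)
    labels.extend(["null"] * n_null)
    amplitudes.extend([0.0] * n_null)
    n_prot = len(labels)
    if n_prot == 0:
        raise ProtascaError("no proteins requested")
    ids = [f"P{i + 1:06d}" for i in range(n_prot)]

    lengths = np.maximum(
        50, np.round(rng.lognormal(mean=np.log(350.0), sigma=0.4, size=n_prot))
    ).astype(int)
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_prot)

    cells = [(t, g) for t in TIME_POINTS for g in TEMPERATURES]
    tmpl = np.stack([templates[lab] for lab in labels])          # prot x 12
    latent = baseline[:, None] + np.asarray(amplitudes)[:, None] * tmpl

    sample_rows = []
    count_cols: dict[str, np.ndarray] = {}
    log2_cols: dict[str, np.ndarray] = {}
    rep_names = [chr(ord("A") + r) for r in range(n_replicates)]
    for ci, (t, g) in enumerate(cells):
        for rep in rep_names:
            sid = f"T{t}_{int(g)}C_{rep}"
            log2_vals = latent[:, ci]
            if noise_sd > 0:
                log2_vals = log2_vals + rng.normal(0.0, noise_sd, size=n_prot)
            weights = np.exp2(log2_vals) * lengths
            probs = weights / weights.sum()
            count_cols[sid] = rng.multinomial(total_spectra, probs)
            log2_cols[sid] = log2_vals
            sample_rows.append({"sample_id": sid, "time_dpf": t,
                                "temperature_c": g, "replicate_id": rep})

    counts = pd.DataFrame(count_cols, index=pd.Index(ids, name="protein_id"))
    table = SpectralCountTable(counts=counts,
                               lengths=pd.Series(lengths, index=counts.index))
    design = SampleDesign(pd.DataFrame(sample_rows))
    cell_ids = [f"T{t}_{int(g)}C" for t, g in cells]
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=counts.index, name="archetype"),
        params={"noise_sd": noise_sd, "n_null": n_null,
                "total_spectra": total_spectra,
                "baseline_log2_mean": baseline_log2_mean,
                "baseline_log2_sd": baseline_log2_sd,
                "specs": [(s.name, s.n_proteins, s.amplitude) for s in specs]},
        seed=seed,
        latent_log2=pd.DataFrame(latent, index=counts.index, columns=cell_ids),
        log2_replicates=pd.DataFrame(log2_cols, index=counts.index),
    )
    return table, design, truth


def log2_replicate_matrix(truth: SyntheticTruth) -> AbundanceMatrix:
    """The generated log2 abundance surface (latent + replicate noise) as an
    :class:`AbundanceMatrix`, for analyses that start from log2 values rather
    than from the multinomially sampled spectral counts."""
    if truth.log2_replicates is None:
        raise ProtascaError("truth carries no log2 replicate matrix")
    return AbundanceMatrix(values=truth.log2_replicates.copy(), scale_tag="log2")


def score_recovery(truth: SyntheticTruth,
                   selection: frozenset[str] | LoadingsSelection | None = None,
                   clades: CladeAssignment | None = None,
                   planted_names: tuple[str, ...] | None = None) -> dict:
    """Precision/recall of planted proteins in a selection and adjusted Rand
    index between planted archetype labels and clade labels.

    ``planted_names`` restricts "planted" to a subset of archetypes (e.g.
    the temporal ones when scoring the time-effect selection). The ARI is
    computed over the clustered proteins only.
    """
    planted = (truth.planted if planted_names is None
               else truth.planted_with(planted_names))
    out: dict = {}
    if selection is not None:
        sel = (selection.selected if isinstance(selection, LoadingsSelection)
               else frozenset(selection))
        unknown = sel - frozenset(truth.labels.index)
        if unknown:
            raise ProtascaError(
                f"selection ids not in truth: {sorted(unknown)[:5]} ...")
        tp = len(sel & planted)
        out["precision"] = tp / len(sel) if sel else float("nan")
        out["recall"] = tp / len(planted) if planted else float("nan")
        out["n_selected"] = len(sel)
        out["per_archetype_recall"] = {
            name: (len(sel & truth.planted_with((name,)))
                   / max(1, (truth.labels == name).sum()))
            for name in sorted(set(truth.labels) - {"null"})
        }
    if clades is not None:
        ids = [p for p in clades.labels.index if p in truth.labels.index]
        if len(ids) != len(clades.labels):
            missing = set(clades.labels.index) - set(ids)
            raise ProtascaError(
                f"clustered ids not in truth: {sorted(missing)[:5]} ...")
        out["ari"] = float(adjusted_rand_score(
            truth.labels.loc[ids].to_numpy(), clades.labels.loc[ids].to_numpy()))
        out["n_clades"] = clades.n_clades
    return out


def settlement_proportion(settled_count: int, transferred_count: int) -> float:
    """Percentage of transferred larvae that settled, to one decimal place."""
    if transferred_count <= 0:
        raise ProtascaError("transferred_count must be positive")
    if not 0 <= settled_count <= transferred_count:
        raise ProtascaError("need 0 <= settled_count <= transferred_count")
    return round(100.0 * settled_count / transferred_count, 1)
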