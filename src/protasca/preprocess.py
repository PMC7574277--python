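"""NSAF quantification and the preprocessing chain.

The normalized spectral abundance factor for protein *p* in sample *s* is

    NSAF(p, s) = (SpC(p, s) / L(p)) / sum_q (SpC(q, s) / L(q))

with SpC the spectral count and L the protein length in residues, so each
sample column sums to one. The chain applied before any multivariate
analysis is: NSAF -> technical-replicate averaging -> zero replacement
(zeros set to a fraction, default 1/8, of the global minimum nonzero value)
-> log2 -> optional per-protein autoscaling for clustering and heatmaps.

Averaging is done on the NSAF scale before the log transform; the log of an
average differs from the average of logs, so the order is fixed here and
documented rather than left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ProtascaError, RunRecord, SampleDesign, SpectralCountTable


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables for the preprocessing chain.

    zero_replacement_fraction
        Zeros become this fraction of the global minimum nonzero abundance;
        default 1/8.
    autoscale_ddof
        Degrees of freedom for the row standard deviation in autoscaling
        (0 = population convention, the default; 1 = sample convention).
    """

    zero_replacement_fraction: float = 0.125
    autoscale_ddof: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.zero_replacement_fraction < 1.0:
            raise ProtascaError("zero_replacement_fraction must be in (0, 1)")
        if self.autoscale_ddof not in (0, 1):
            raise ProtascaError("autoscale_ddof must be 0 or 1")


def compute_nsaf(counts: SpectralCountTable,
                 adjust_scale: float | None = None) -> AbundanceMatrix:
    """Spectral counts -> NSAF; each sample column sums to 1.

    With ``adjust_scale`` every value is multiplied by that constant and the
    result is tagged ``adjusted_nsaf`` (matching quantification exports that
    rescale NSAF before writing).
    """
    spc = counts.counts.to_numpy(dtype=float)
    lengths = counts.lengths.to_numpy(dtype=float)[:, None]
    saf = spc / lengths
    col_sums = saf.sum(axis=0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_cols.size:
        names = [counts.sample_ids[i] for i in zero_cols]
        raise ProtascaError(f"all-zero sample column(s): {names}")
    nsaf = saf / col_sums
    tag = "nsaf"
    if adjust_scale is not None:
        if adjust_scale <= 0:
            raise ProtascaError("adjust_scale must be positive")
        nsaf = nsaf * adjust_scale
        tag = "adjusted_nsaf"
    values = pd.DataFrame(nsaf, index=counts.counts.index,
                          columns=counts.counts.columns)
    return AbundanceMatrix(values=values, scale_tag=tag)


def replace_zeros(m: AbundanceMatrix,
                  params: PreprocessParams = PreprocessParams(),
                  run_record: RunRecord | None = None) -> AbundanceMatrix:
    """Replace zero cells by ``fraction x (global minimum nonzero value)``.

    Nonzero cells are untouched; with a minimum nonzero of 0.8 and the
    default fraction 1/8 zeros become 0.1. The replacement constant is
    logged to the run record.
    """
    if m.scale_tag not in ("nsaf", "adjusted_nsaf"):
        raise ProtascaError(
            f"zero replacement applies to (adjusted) NSAF, got {m.scale_tag!r}")
    vals = m.values.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ProtascaError("matrix is entirely zero; nothing to replace with")
    if (vals == 0).sum() == 0:
        return m
    replacement = params.zero_replacement_fraction * nonzero.min()
    out = m.values.where(m.values != 0, replacement)
    if run_record is not None:
        run_record.log(f"zero replacement: min nonzero {nonzero.min():.6g}, "
                       f"constant {replacement:.6g}")
    return AbundanceMatrix(values=out, scale_tag=m.scale_tag)


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log base 2; requires strictly positive values."""
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ProtascaError(
            f"non-positive value at protein {m.protein_ids[r]!r}, sample "
            f"{m.sample_ids[c]!r}; run zero replacement before log2")
    return AbundanceMatrix(values=np.log2(m.values), scale_tag="log2")


def average_technical_replicates(
    m: AbundanceMatrix, design: SampleDesign,
    run_record: RunRecord | None = None,
) -> tuple[AbundanceMatrix, SampleDesign]:
    """Average technical replicates into one column per biological sample.

    Replicate groups are samples sharing (time_dpf, temperature_c). The
    collapsed design keeps one row per group with ``replicate_id`` set to
    ``"avg"`` and a generated sample id ``T<dpf>_<temp>C``. Singleton groups
    pass through with a logged note.
    """
    missing = [s for s in design.sample_ids if s not in m.values.columns]
    if missing:
        raise ProtascaError(f"design samples absent from matrix: {missing}")
    groups = design.table.groupby(["time_dpf", "temperature_c"], sort=True)
    cols: dict[str, pd.Series] = {}
    rows = []
    singletons = []
    for (t, temp), sub in groups:
        new_id = f"T{t}_{_fmt_temp(temp)}C"
        member_ids = list(sub["sample_id"])
        if len(member_ids) == 1:
            singletons.append(member_ids[0])
        cols[new_id] = m.values[member_ids].mean(axis=1)
        rows.append({"sample_id": new_id, "time_dpf": t,
                     "temperature_c": temp, "replicate_id": "avg"})
    if singletons and run_record is not None:
        run_record.log(f"replicate averaging: singleton groups for {singletons}")
    averaged = AbundanceMatrix(values=pd.DataFrame(cols), scale_tag=m.scale_tag)
    return averaged, SampleDesign(pd.DataFrame(rows))


def _fmt_temp(temp: float) -> str:
    return str(int(temp)) if float(temp).is_integer() else str(temp)


def autoscale_rows(m: AbundanceMatrix,
                   params: PreprocessParams = PreprocessParams()) -> AbundanceMatrix:
    """Standardize each protein row to mean 0, sd 1 across samples.

    Zero-variance rows are left at 0 and flagged on the returned matrix
    instead of dividing by zero.
    """
    if m.values.shape[1] < 2:
        raise ProtascaError("autoscaling needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=params.autoscale_ddof, keepdims=True)
    flat = sd[:, 0] == 0
    sd_safe = np.where(flat[:, None], 1.0, sd)
    scaled = (vals - mean) / sd_safe
    scaled[flat, :] = 0.0
    flagged = tuple(np.asarray(m.protein_ids)[flat])
    out = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return AbundanceMatrix(values=out, scale_tag="autoscaled", flagged_rows=flagged)
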