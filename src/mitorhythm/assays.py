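"""Derived assay quantities: Mito Stress respiration parameters from
extracellular-flux (OCR) traces, and ΔΔCt relative qPCR fold changes.

A standard Mito Stress run measures oxygen consumption rate (OCR) in
four phases — baseline, then after sequential injection of oligomycin
(ATP-synthase inhibitor), FCCP (uncoupler) and rotenone/antimycin A
(complex I/III inhibitors).  The rotenone/antimycin phase estimates
non-mitochondrial oxygen consumption, which is subtracted from the
others:

* basal respiration   = last baseline measurement − non-mitochondrial
* maximal respiration = max of FCCP phase − non-mitochondrial
* spare respiratory capacity (SRC) = maximal − basal
  (also reported as 100·maximal/basal, the percentage convention)

ΔΔCt quantification: per sample, ΔCt = Ct(target) − Ct(reference gene);
ΔΔCt = ΔCt − mean ΔCt of the control condition; fold change = 2^(−ΔΔCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ParameterError

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")


class PhaseError(ParameterError):
    """A required injection phase is missing or out of order."""


@dataclass(frozen=True)
class OCRTrace:
    """Oxygen-consumption trace with its injection schedule.

    ``phases`` assigns each measurement to one of :data:`PHASES`, which
    must appear contiguously in that fixed order with at least one
    measurement each.  ``times_min`` is optional and informational.
    """

    values: np.ndarray
    phases: np.ndarray
    times_min: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        ph = np.asarray(self.phases, dtype=object)
        if v.shape != ph.shape or v.ndim != 1:
            raise ParameterError("values and phases must be 1-D and of equal length")
        seen = [p for i, p in enumerate(ph) if i == 0 or ph[i - 1] != p]
        missing = [p for p in PHASES if p not in ph]
        if missing:
            raise PhaseError(f"missing phase(s): {', '.join(missing)}")
        if tuple(seen) != PHASES:
            raise PhaseError(f"phases must appear once each in order {PHASES}, got {tuple(seen)}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "phases", ph)
        if self.times_min is not None:
            object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))

    def phase_values(self, phase: str) -> np.ndarray:
        return self.values[self.phases == phase]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OCRTrace":
        times = df["time_min"].to_numpy(float) if "time_min" in df.columns else None
        return cls(df["ocr"].to_numpy(float), df["phase"].to_numpy(object), times)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"ocr": self.values, "phase": self.phases})
        if self.times_min is not None:
            out.insert(0, "time_min", self.times_min)
        return out


@dataclass(frozen=True)
class MitoStressParams:
    """Respiration parameters derived from one OCR trace."""

    non_mito: float
    basal: float
    maximal: float
    spare_capacity: float
    src_percent: float
    quality_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "non_mito": self.non_mito,
            "basal": self.basal,
            "maximal": self.maximal,
            "spare_capacity": self.spare_capacity,
            "src_percent": self.src_percent,
            "quality_warning": self.quality_warning,
        }


def mito_stress_params(trace: OCRTrace, basal_stat: str = "last") -> MitoStressParams:
    """Derive Mito Stress respiration parameters from a 4-phase trace.

    ``basal_stat`` chooses the baseline summary: ``"last"`` (default;
    the last, most equilibrated pre-injection measurement) or ``"mean"``.
    A negative basal after non-mitochondrial correction is returned
    as-is with ``quality_warning=True``, never clamped.
    """
    if basal_stat not in ("last", "mean"):
        raise ParameterError(f"basal_stat must be 'last' or 'mean', got {basal_stat!r}")
    non_mito = float(np.mean(trace.phase_values("rot_aa")))
    baseline = trace.phase_values("baseline")
    raw_basal = float(baseline[-1]) if basal_stat == "last" else float(baseline.mean())
    basal = raw_basal - non_mito
    maximal = float(np.max(trace.phase_values("fccp"))) - non_mito
    spare = maximal - basal
    src_percent = 100.0 * maximal / basal if basal > 0 else float("nan")
    return MitoStressParams(
        non_mito=non_mito,
        basal=basal,
        maximal=maximal,
        spare_capacity=spare,
        src_percent=src_percent,
        quality_warning=basal < 0,
    )


def ddct_fold_change(
    ct: pd.DataFrame,
    control_condition: str,
    sample_col: str = "sample",
    condition_col: str = "condition",
    gene_col: str = "gene",
    reference_col: str = "is_reference",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """ΔΔCt fold changes for every target gene against a reference gene.

    Expects one reference-gene Ct per sample (rows with
    ``is_reference == True``).  Fold changes are relative to the mean
    ΔCt of ``control_condition`` per target gene, so the control group's
    fold changes geometric-mean to 1.

    Returns a table with columns sample, condition, gene, delta_ct,
    delta_delta_ct, fold_change.
    """
    required = {sample_col, condition_col, gene_col, reference_col, ct_col}
    missing_cols = required - set(ct.columns)
    if missing_cols:
        raise ParameterError(f"Ct table lacks column(s): {sorted(missing_cols)}")
    if not np.all(np.isfinite(ct[ct_col].to_numpy(float))):
        raise ParameterError("Ct values must be finite")

    refs = ct[ct[reference_col].astype(bool)]
    targets = ct[~ct[reference_col].astype(bool)]
    ref_ct = refs.groupby(sample_col)[ct_col].mean()

    missing = sorted(set(targets[sample_col]) - set(ref_ct.index))
    if missing:
        raise ParameterError(f"missing reference-gene Ct for sample(s): {', '.join(map(str, missing))}")
    if control_condition not in set(ct[condition_col]):
        raise ParameterError(f"control condition {control_condition!r} not present in table")

    out = targets[[sample_col, condition_col, gene_col]].copy()
    out["delta_ct"] = targets[ct_col].to_numpy(float) - ref_ct.loc[targets[sample_col]].to_numpy(float)
    control_mean = (
        out[out[condition_col] == control_condition].groupby(gene_col)["delta_ct"].mean()
    )
    genes_wo_control = sorted(set(out[gene_col]) - set(control_mean.index))
    if genes_wo_control:
        raise ParameterError(
            f"no control-condition rows for gene(s): {', '.join(map(str, genes_wo_control))}"
        )
    out["delta_delta_ct"] = out["delta_ct"] - control_mean.loc[out[gene_col]].to_numpy(float)
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    return out.reset_index(drop=True)
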