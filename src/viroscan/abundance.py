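"""Viral abundance quantification.

Three modes:

* ``qpcr_relative``  — E_v^(-Ct_virus) / E_r^(-Ct_reference), the classic
  efficiency-corrected ratio against an endogenous reference target
  (named "L23a" by default); E = 2 at 100% primer efficiency.
* ``copies_per_ug``  — absolute genome copies per microgram of input RNA,
  inverted through a standard curve (Ct vs log10 copies).
* ``count_relative`` — read-count ratio against the reference target's
  counts, with a pseudocount to keep log10 finite for absent viruses.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

DEFAULT_REFERENCE = "L23a"
MAX_EFFICIENCY = 2.2


class ParameterError(ValueError):
    pass


class InvalidCurveError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target: str
    ct: float | None  # None = no amplification
    efficiency_E: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency_E <= MAX_EFFICIENCY):
            raise ParameterError(
                f"efficiency {self.efficiency_E} outside (1, {MAX_EFFICIENCY}]"
            )
        if self.ct is not None and self.ct <= 0:
            raise ParameterError(f"Ct must be positive, got {self.ct}")

    @property
    def no_amplification(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(copies)."""

    target: str
    slope: float
    intercept: float
    r_squared: float
    valid: bool = True

    @property
    def implied_efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)


@dataclass(frozen=True)
class AbundanceEstimate:
    sample_id: str
    virus: str
    mode: str  # qpcr_relative | copies_per_ug | count_relative
    value: float
    log_value: float
    reference: str = ""
    no_amplification: bool = False


def relative_abundance_qpcr(
    virus_ct: float | None,
    ref_ct: float,
    E_virus: float = 2.0,
    E_ref: float = 2.0,
    sample_id: str = "",
    virus: str = "",
    reference: str = DEFAULT_REFERENCE,
) -> AbundanceEstimate:
    """Efficiency-corrected relative abundance E_v^-Ct_v / E_r^-Ct_r.

    A ``virus_ct`` of None (no amplification) yields value 0 with the
    no-amplification flag set."""
    for E in (E_virus, E_ref):
        if not (1.0 < E <= MAX_EFFICIENCY):
            raise ParameterError(f"amplification factor {E} outside (1, {MAX_EFFICIENCY}]")
    if ref_ct is None or ref_ct <= 0:
        raise ParameterError("reference Ct must be positive")
    if virus_ct is None:
        return AbundanceEstimate(
            sample_id, virus, "qpcr_relative", 0.0, -math.inf, reference, True
        )
    if virus_ct <= 0:
        raise ParameterError(f"Ct must be positive, got {virus_ct}")
    # computed in log domain for numeric range
    log_value = ref_ct * math.log10(E_ref) - virus_ct * math.log10(E_virus)
    return AbundanceEstimate(
        sample_id, virus, "qpcr_relative", 10.0 ** log_value, log_value, reference
    )


def fit_standard_curve(
    copies: Sequence[float], cts: Sequence[float], target: str = ""
) -> StandardCurve:
    """Fit Ct against log10(copies) by least squares over a dilution series."""
    if len(copies) != len(cts):
        raise ParameterError("copies and cts must have equal length")
    if len(copies) < 3:
        raise ParameterError(f"need >= 3 dilution points, got {len(copies)}")
    if any(c <= 0 for c in copies):
        raise ParameterError("copy numbers must be strictly positive")
    x = np.log10(np.asarray(copies, dtype=float))
    y = np.asarray(cts, dtype=float)
    res = sstats.linregress(x, y)
    valid = res.slope < 0
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid=valid,
    )


def copies_per_ug(
    ct: float,
    curve: StandardCurve,
    rna_input_ug: float = 1.0,
    sample_id: str = "",
    virus: str = "",
) -> AbundanceEstimate:
    """Invert a standard curve: copies = 10^((ct - intercept)/slope), scaled
    to genome copies per microgram of input RNA."""
    if not curve.valid:
        raise InvalidCurveError(f"standard curve for {curve.target!r} is invalid")
    if rna_input_ug <= 0:
        raise ParameterError("rna_input_ug must be > 0")
    log_copies = (ct - curve.intercept) / curve.slope
    value = 10.0 ** log_copies / rna_input_ug
    return AbundanceEstimate(
        sample_id, virus or curve.target, "copies_per_ug", value, math.log10(value), ""
    )


def relative_abundance_counts(
    virus_counts: float,
    ref_counts: float,
    pseudocount: float = 1.0,
    sample_id: str = "",
    virus: str = "",
    reference: str = DEFAULT_REFERENCE,
) -> AbundanceEstimate:
    """Read-count abundance relative to the reference target's counts."""
    if ref_counts <= 0:
        raise ParameterError(f"reference counts must be > 0, got {ref_counts}")
    if virus_counts < 0:
        raise ParameterError("virus counts must be >= 0")
    value = (virus_counts + pseudocount) / (ref_counts + pseudocount)
    log_value = math.log10(value) if value > 0 else -math.inf
    return AbundanceEstimate(sample_id, virus, "count_relative", value, log_value, reference)


# ---------------------------------------------------------------------------
# table-level drivers

def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Ct TSV with columns sample, target, ct, efficiency (ct blank or 'NA'
    means no amplification; efficiency blank means 2)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "target", "ct"}
        if not required.issubset(reader.fieldnames or []):
            raise ParameterError(f"Ct table needs columns {sorted(required)}")
        for row in reader:
            raw_ct = (row["ct"] or "").strip()
            ct = None if raw_ct in ("", "NA", "nan") else float(raw_ct)
            eff = float(row.get("efficiency") or 2.0)
            out.append(QpcrMeasurement(row["sample"], row["target"], ct, eff))
    return out


def qpcr_table_abundance(
    measurements: Sequence[QpcrMeasurement], reference: str = DEFAULT_REFERENCE
) -> list[AbundanceEstimate]:
    """Relative abundance of every non-reference target in every sample."""
    refs = {
        m.sample_id: m for m in measurements if m.target == reference and m.ct is not None
    }
    out = []
    for m in measurements:
        if m.target == reference:
            continue
        if m.sample_id not in refs:
            raise ParameterError(
                f"sample {m.sample_id!r}: no amplified reference target {reference!r}"
            )
        r = refs[m.sample_id]
        out.append(
            relative_abundance_qpcr(
                m.ct, r.ct, m.efficiency_E, r.efficiency_E,
                sample_id=m.sample_id, virus=m.target, reference=reference,
            )
        )
    return out


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "counts"}
    if not required.issubset(df.columns):
        raise ParameterError(f"counts table needs columns {sorted(required)}")
    return df


def counts_table_abundance(
    df: pd.DataFrame, reference: str = DEFAULT_REFERENCE, pseudocount: float = 1.0
) -> list[AbundanceEstimate]:
    out = []
    for sample, group in df.groupby("sample", sort=True):
        ref_rows = group[group["target"] == reference]
        if ref_rows.empty:
            raise ParameterError(f"sample {sample!r}: missing reference target {reference!r}")
        ref_counts = float(ref_rows["counts"].iloc[0])
        for _, row in group.iterrows():
            if row["target"] == reference:
                continue
            out.append(
                relative_abundance_counts(
                    float(row["counts"]), ref_counts, pseudocount,
                    sample_id=str(sample), virus=str(row["target"]), reference=reference,
                )
            )
    return out


def prevalence_matrix(estimates: Sequence[AbundanceEstimate]) -> pd.DataFrame:
    """Samples x viruses matrix of abundance values (0 = not detected)."""
    if not estimates:
        return pd.DataFrame()
    df = pd.DataFrame(
        [{"sample": e.sample_id, "virus": e.virus, "value": e.value} for e in estimates]
    )
    return df.pivot_table(index="sample", columns="virus", values="value", fill_value=0.0)


def write_abundance(estimates: Sequence[AbundanceEstimate], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "virus", "mode", "value", "log10_value", "reference", "no_amplification"])
        for e in estimates:
            w.writerow(
                [
                    e.sample_id,
                    e.virus,
                    e.mode,
                    f"{e.value:.6g}",
                    "-inf" if e.log_value == -math.inf else f"{e.log_value:.6g}",
                    e.reference,
                    str(e.no_amplification).lower(),
                ]
            )
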