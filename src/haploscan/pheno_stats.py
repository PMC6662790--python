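"""ECG/QTc computation and cohort frequency statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "bazett_qtc",
    "bazett_qtc_from_hr",
    "carrier_allele_frequency",
    "fold_enrichment",
    "GroupSummary",
    "group_qtc_summary",
    "CarrierStats",
    "carrier_stats",
]

# QTc prolongation cut-offs (ms); clinical convention, not derived here.
QTC_CUTOFF_MALE_MS = 450.0
QTC_CUTOFF_FEMALE_MS = 470.0


def bazett_qtc(qt_ms, rr_s):
    """Heart-rate-corrected QT: ``QTc = QT / sqrt(RR)`` with RR in seconds.

    Accepts scalars or arrays; strictly decreasing in RR and linear in QT.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    if (qt <= 0).any() or (rr <= 0).any():
        raise ValidationError("QT and RR must be positive")
    out = qt / np.sqrt(rr)
    return float(out) if out.ndim == 0 else out


def bazett_qtc_from_hr(qt_ms, heart_rate_bpm):
    """Convenience overload taking heart rate: ``RR = 60 / HR`` seconds."""
    hr = np.asarray(heart_rate_bpm, dtype=float)
    if (hr <= 0).any():
        raise ValidationError("heart rate must be positive")
    return bazett_qtc(qt_ms, 60.0 / hr)


def carrier_allele_frequency(n_het_carriers: int, n_individuals: int) -> float:
    """Allele frequency of a variant seen only in heterozygotes:
    ``n_het / (2 * n_individuals)`` (diploid denominator)."""
    if n_individuals <= 0:
        raise ValidationError("cohort size must be positive")
    if not (0 <= n_het_carriers <= n_individuals):
        raise ValidationError("carrier count must be between 0 and cohort size")
    return n_het_carriers / (2 * n_individuals)


def fold_enrichment(f_cohort: float, f_reference: float) -> float:
    """Ratio of cohort to reference allele frequency."""
    if f_reference <= 0:
        raise ValidationError("reference frequency must be positive")
    if f_cohort < 0:
        raise ValidationError("cohort frequency must be non-negative")
    return f_cohort / f_reference


@dataclass
class GroupSummary:
    n: int
    mean_ms: float
    min_ms: float
    max_ms: float


def group_qtc_summary(
    ecg: pd.DataFrame,
    carrier_labels: dict[str, bool],
    sex: dict[str, int] | None = None,
    cutoff_ms: float = QTC_CUTOFF_MALE_MS,
    cutoff_female_ms: float = QTC_CUTOFF_FEMALE_MS,
) -> dict:
    """Per-group QTc mean and range, plus carrier penetrance at a cut-off.

    ``ecg`` needs columns ``id`` and either ``qtc_ms`` or (``qt_ms``,
    ``rr_s``).  Every record's id must appear in ``carrier_labels``.
    Penetrance is the fraction of carriers whose QTc exceeds the cut-off
    (sex-specific 450/470 ms when a sex map is given, 1 = male 2 = female).
    An empty group is reported as absent rather than an error.
    """
    if "qtc_ms" in ecg.columns:
        qtc = ecg["qtc_ms"].to_numpy(float)
    else:
        qtc = bazett_qtc(ecg["qt_ms"].to_numpy(float), ecg["rr_s"].to_numpy(float))
    ids = ecg["id"].astype(str).tolist()
    missing = [i for i in ids if i not in carrier_labels]
    if missing:
        raise ValidationError(f"no carrier label for: {missing[:5]}")
    is_carrier = np.array([carrier_labels[i] for i in ids], dtype=bool)

    out: dict = {"groups": {}}
    for name, mask in (("carriers", is_carrier), ("noncarriers", ~is_carrier)):
        if mask.any():
            vals = qtc[mask]
            out["groups"][name] = GroupSummary(
                n=int(mask.sum()),
                mean_ms=float(vals.mean()),
                min_ms=float(vals.min()),
                max_ms=float(vals.max()),
            )
    if is_carrier.any():
        if sex is not None:
            cut = np.array(
                [
                    cutoff_female_ms if sex.get(i) == 2 else cutoff_ms
                    for i in ids
                ]
            )
        else:
            cut = np.full(len(ids), cutoff_ms)
        prolonged = (qtc > cut) & is_carrier
        out["penetrance"] = float(prolonged.sum() / is_carrier.sum())
    else:
        out["penetrance"] = None
    return out


@dataclass
class CarrierStats:
    n_carriers: int
    n_individuals: int
    allele_frequency: float
    reference_frequency: float
    fold_enrichment: float
    qtc: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "n_carriers": self.n_carriers,
            "n_individuals": self.n_individuals,
            "allele_frequency": self.allele_frequency,
            "reference_frequency": self.reference_frequency,
            "fold_enrichment": self.fold_enrichment,
        }
        if self.qtc is not None:
            groups = {
                name: vars(g) for name, g in self.qtc["groups"].items()
            }
            d["qtc"] = {"groups": groups, "penetrance": self.qtc["penetrance"]}
        return d


def carrier_stats(
    n_carriers: int,
    n_individuals: int,
    reference_frequency: float,
    ecg: pd.DataFrame | None = None,
    carrier_labels: dict[str, bool] | None = None,
    sex: dict[str, int] | None = None,
) -> CarrierStats:
    """Bundle the headline statistics for a carrier set."""
    freq = carrier_allele_frequency(n_carriers, n_individuals)
    stats = CarrierStats(
        n_carriers=n_carriers,
        n_individuals=n_individuals,
        allele_frequency=freq,
        reference_frequency=reference_frequency,
        fold_enrichment=fold_enrichment(freq, reference_frequency),
    )
    if ecg is not None and carrier_labels is not None:
        stats.qtc = group_qtc_summary(ecg, carrier_labels, sex=sex)
    return stats
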