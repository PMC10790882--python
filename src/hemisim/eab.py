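"""EAB (equal/above/below) within-subject comparison against an IQR band.

For every driving or gaze measure, a subject's value under simulated
hemianopia is compared with that subject's own normal-vision (NV) value:
the interquartile range of all participants' NV values (in the same
intersection type) is computed, half of it is added and subtracted around
the subject's NV value, and the impaired-condition value is rated ``equal``
when it falls inside the closed band, ``above`` or ``below`` otherwise.
A modified variant rates blind-side fixation counts against a band built
from the seeing-side sample and centered on the subject's seeing-side value.

Quartiles use linear interpolation of order statistics (numpy's default,
type 7); the estimator is configurable because the choice is a convention,
not a property of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import percentage

__all__ = ["EABBand", "EABResult", "nv_band", "classify",
           "classify_blind_seeing", "eab_table", "lane_buffer_counts",
           "blind_seeing_fixation_table"]


@dataclass
class EABBand:
    center: float
    half_width: float

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width


@dataclass
class EABResult:
    classification: str  # equal | above | below | missing
    value: float
    band: EABBand


def nv_band(subject_nv: float, sample_nv, quantile_method: str = "linear") -> EABBand:
    """Half-IQR band of the reference sample, centered on the subject.

    ``sample_nv`` is the NV sample over all participants (the subject's own
    value included); missing values are dropped with a warning.
    """
    sample = np.asarray(sample_nv, dtype=float)
    finite = np.isfinite(sample)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} missing reference values")
        sample = sample[finite]
    if sample.size < 2:
        raise ValueError("reference sample needs at least 2 finite values")
    q1, q3 = np.quantile(sample, [0.25, 0.75], method=quantile_method)
    return EABBand(center=float(subject_nv), half_width=float(q3 - q1) / 2.0)


def classify(value: float, band: EABBand) -> EABResult:
    """Three-way classification against the closed band [lower, upper]."""
    if value is None or not np.isfinite(value):
        return EABResult("missing", np.nan, band)
    if value > band.upper:
        cls = "above"
    elif value < band.lower:
        cls = "below"
    else:
        cls = "equal"
    return EABResult(cls, float(value), band)


def classify_blind_seeing(blind_value: float, seeing_value: float,
                          sample_seeing,
                          quantile_method: str = "linear") -> EABResult:
    """Blind- vs seeing-side variant: band from the seeing-side sample,
    centered on the subject's seeing-side value; ``above`` means the blind
    side outnumbers the seeing side."""
    band = nv_band(seeing_value, sample_seeing, quantile_method)
    return classify(blind_value, band)


def eab_table(records: pd.DataFrame, metric: str,
              quantile_method: str = "linear") -> dict:
    """Classify every impaired-condition scenario of a study for one metric.

    ``records`` is the scenario-metrics table (columns ``subject``,
    ``condition``, ``intersection`` and the metric).  Classification is
    performed per intersection type against that intersection's NV sample.
    Returns ``{"classifications": DataFrame, "counts": DataFrame}`` where
    counts hold equal/above/below/missing per condition plus a pooled row,
    with percentages over the classified scenarios.
    """
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} not in records")
    rows = []
    for intersection, group in records.groupby("intersection", sort=True):
        nv = group[group["condition"] == "NV"].set_index("subject")[metric]
        sample_nv = nv.to_numpy(dtype=float)
        sample_nv = sample_nv[np.isfinite(sample_nv)]
        for cond in ("LHH", "RHH"):
            sub = group[group["condition"] == cond]
            for _, rec in sub.iterrows():
                subject = rec["subject"]
                value = rec[metric]
                if subject not in nv.index or not np.isfinite(nv[subject]) \
                        or sample_nv.size < 2:
                    rows.append({"subject": subject, "condition": cond,
                                 "intersection": intersection, "value": value,
                                 "classification": "missing",
                                 "lower": np.nan, "upper": np.nan})
                    continue
                band = nv_band(float(nv[subject]), sample_nv, quantile_method)
                res = classify(float(value) if np.isfinite(value) else np.nan,
                               band)
                rows.append({"subject": subject, "condition": cond,
                             "intersection": intersection, "value": value,
                             "classification": res.classification,
                             "lower": band.lower, "upper": band.upper})
    cls = pd.DataFrame(rows)
    return {"classifications": cls, "counts": _count_table(cls)}


def _count_table(cls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = list(cls.groupby("condition", sort=True))
    groups.append(("pooled", cls))
    for cond, group in groups:
        classified = group[group["classification"] != "missing"]
        total = len(classified)
        row = {"condition": cond, "n_classified": total,
               "n_missing": int(len(group) - total)}
        for label in ("equal", "above", "below"):
            k = int((classified["classification"] == label).sum())
            row[label] = k
            row[f"{label}_pct"] = percentage(k, total) if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def lane_buffer_counts(classifications: pd.DataFrame) -> pd.DataFrame:
    """Interpret lane-position EAB classes as blind/seeing-side buffers.

    Lane offset is positive to the right.  Under LHH (left side blind) a
    shift above the NV band moves the vehicle away from the blind side
    (blind-side buffer); under RHH the roles mirror.
    """
    mapping = {
        ("LHH", "above"): "blind", ("LHH", "below"): "seeing",
        ("RHH", "below"): "blind", ("RHH", "above"): "seeing",
    }
    rows = []
    for cond in ("LHH", "RHH"):
        group = classifications[
            (classifications["condition"] == cond)
            & (classifications["classification"] != "missing")
        ]
        total = len(group)
        for side in ("blind", "seeing"):
            k = int(sum(
                mapping.get((cond, c)) == side
                for c in group["classification"]
            ))
            rows.append({"condition": cond, "buffer": side, "k": k, "K": total,
                         "pct": percentage(k, total) if total else float("nan")})
    return pd.DataFrame(rows)


def blind_seeing_fixation_table(records: pd.DataFrame,
                                quantile_method: str = "linear") -> dict:
    """Blind- vs seeing-side fixation-number EAB over a study.

    Per impaired condition and intersection, the reference sample is the
    seeing-side fixation count of all participants in that cell; each
    subject's blind-side count is classified against the half-IQR band
    centered on their own seeing-side count.
    """
    sides = {"LHH": ("fix_n_left", "fix_n_right"),
             "RHH": ("fix_n_right", "fix_n_left")}
    rows = []
    for cond, (blind_col, seeing_col) in sides.items():
        sub = records[records["condition"] == cond]
        for intersection, group in sub.groupby("intersection", sort=True):
            sample_seeing = group[seeing_col].to_numpy(dtype=float)
            sample_seeing = sample_seeing[np.isfinite(sample_seeing)]
            for _, rec in group.iterrows():
                if sample_seeing.size < 2:
                    cls = "missing"
                else:
                    res = classify_blind_seeing(
                        float(rec[blind_col]), float(rec[seeing_col]),
                        sample_seeing, quantile_method,
                    )
                    cls = res.classification
                rows.append({"subject": rec["subject"], "condition": cond,
                             "intersection": intersection,
                             "blind": rec[blind_col], "seeing": rec[seeing_col],
                             "classification": cls})
    cls = pd.DataFrame(rows)
    return {"classifications": cls, "counts": _count_table(cls)}
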