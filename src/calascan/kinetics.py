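"""Specific activity from chromogenic p-NO2-phenyl-ester assays.

Hydrolysis of p-NO2-phenyl fatty-acid esters releases p-nitrophenolate
(epsilon = 18.1 mM^-1 cm^-1), monitored as an absorbance slope in a plate
reader.  Specific activity is

    S.A. [U/mg] = slope / (l x epsilon) x (Vt / Ve) x 1 / [Ce]

with slope in min^-1, path length l in cm, total and enzyme volumes Vt/Ve in
mL and total protein [Ce] in mg/mL; 1 U = 1 umol p-nitrophenolate per minute
(assays at 45 degC).  Relative activity and chain-length selectivity ratios
are simple quotients against a named reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EPSILON_PNP_MM_CM",
    "KineticAssay",
    "ActivityResult",
    "NegativeSlopeWarning",
    "specific_activity",
    "relative_activity",
    "selectivity_ratio",
    "fit_slope",
    "activity_table",
]

EPSILON_PNP_MM_CM = 18.1   # p-NO2-phenolate extinction coefficient, mM^-1 cm^-1


class NegativeSlopeWarning(UserWarning):
    """Fitted initial rate was negative and has been clipped to zero."""


@dataclass(frozen=True)
class KineticAssay:
    """Geometry and inputs of one initial-rate measurement."""

    clone_id: str = ""
    substrate: str = ""            # chain label, e.g. C4 butyrate ... C16 palmitate
    slope: float = 0.0             # absorbance min^-1
    path_length: float = 1.0       # cm
    epsilon: float = EPSILON_PNP_MM_CM
    v_total: float = 0.2           # mL (200 uL reaction)
    v_enzyme: float = 0.02         # mL lysate
    protein_conc: float = 1.0      # mg/mL total protein in lysate
    temperature: float = 45.0      # degC, reference condition

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.path_length <= 0:
            raise ValueError("epsilon and path_length must be positive")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        if not 0 < self.v_enzyme <= self.v_total:
            raise ValueError("require 0 < v_enzyme <= v_total")


@dataclass(frozen=True)
class ActivityResult:
    clone_id: str
    substrate: str
    specific_activity: float          # U/mg
    relative_pct: float | None = None
    selectivity_ratio: float | None = None


def specific_activity(assay: KineticAssay) -> float:
    """Specific activity in U/mg; negative slopes clip to 0 with a warning."""
    slope = assay.slope
    if slope < 0:
        warnings.warn(f"clone {assay.clone_id or '?'} / {assay.substrate or '?'}: "
                      f"negative slope {slope:.4g} clipped to 0",
                      NegativeSlopeWarning, stacklevel=2)
        slope = 0.0
    return (slope / (assay.path_length * assay.epsilon)
            * (assay.v_total / assay.v_enzyme) / assay.protein_conc)


def relative_activity(sa: float, sa_ref: float) -> float:
    """Activity as a percentage of a reference specific activity."""
    if sa_ref <= 0:
        raise ValueError("reference specific activity must be positive")
    return 100.0 * sa / sa_ref


def selectivity_ratio(sa_a: float, sa_b: float) -> float:
    """Chain-length selectivity: specific activity ratio between two substrates."""
    if sa_b == 0:
        raise ZeroDivisionError("selectivity ratio undefined: denominator activity is 0")
    return sa_a / sa_b


def fit_slope(times_min: np.ndarray, absorbance: np.ndarray,
              window: tuple[float, float] | None = None) -> tuple[float, float]:
    """OLS initial-rate fit; returns (slope per min, slope standard error).

    ``window`` restricts the fit to a [t0, t1] linear range.
    """
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, a = t[keep], a[keep]
    if t.size < 2:
        raise ValueError("need at least two points to fit a slope")
    (slope, intercept), cov = np.polyfit(t, a, 1, cov=True) if t.size > 2 else (
        np.polyfit(t, a, 1), np.full((2, 2), np.nan))
    return float(slope), float(np.sqrt(cov[0, 0]))


def activity_table(assays: list[KineticAssay], reference_clone: str,
                   reference_substrate: str) -> pd.DataFrame:
    """Tabulate S.A., % of the reference clone/substrate, and selectivity.

    ``relative_pct`` is against the reference clone's activity on the
    reference substrate (the convention used when reporting variant panels);
    ``selectivity_vs_ref_substrate`` is each clone's activity on a substrate
    divided by the same clone's activity on the reference substrate.
    """
    sa = {(a.clone_id, a.substrate): specific_activity(a) for a in assays}
    ref_key = (reference_clone, reference_substrate)
    if ref_key not in sa:
        raise KeyError(f"reference assay {ref_key} not present")
    sa_ref = sa[ref_key]
    rows = []
    for a in assays:
        value = sa[(a.clone_id, a.substrate)]
        own_ref = sa.get((a.clone_id, reference_substrate))
        rows.append({
            "clone_id": a.clone_id,
            "substrate": a.substrate,
            "specific_activity_u_mg": value,
            "relative_pct": relative_activity(value, sa_ref) if sa_ref > 0 else np.nan,
            "selectivity_vs_ref_substrate":
                (selectivity_ratio(value, own_ref)
                 if own_ref not in (None, 0) else np.nan),
        })
    return pd.DataFrame(rows)
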