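"""Hit-calling statistics for the genome-wide cytosolic-pH screen.

Each replicate batch is normalised internally: a strain's mean pH is
expressed as a Z-value, the number of wild-type standard deviations it sits
from the wild-type mean *of that batch*.  Candidate hits must reach |Z| >= 2
in one of the two primary screens and |Z| >= 1, with the same sign, in the
other.  Candidates are confirmed by a two-tailed equal-variance t-test of
their rescreening Z-values against the wild-type Z pool (P < 0.01), and
outlier-driven calls are removed by a Jackknife re-test that discards each
strain's single lowest and highest replicate and requires the trimmed
P-value to stay <= 0.1.

The same machinery profiles mutants across stress conditions (external pH
3.0 / 7.5, respiratory carbon source) and estimates the screen's false
negative rate from strains of known direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BatchError, ValidationError

__all__ = [
    "HitCall", "replicate_z_values", "select_candidates", "two_sample_t",
    "confirm_hits", "jackknife_retest", "trim_extremes", "condition_profile",
    "cross_condition_sets", "false_negative_rate",
]

STATUS_VALUES = (
    "not_candidate", "candidate", "confirmed", "discarded_jackknife", "nd",
)


@dataclass(frozen=True)
class HitCall:
    """Outcome of the confirmation test for one strain (optionally per condition)."""

    strain_id: str
    direction: str | None          # "low" | "high" | None (undetermined)
    p_value: float
    mean_z: float
    n_replicates: int
    status: str
    p_jackknife: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUS_VALUES:
            raise ValidationError(f"unknown status {self.status!r}")


def replicate_z_values(
    batch: pd.DataFrame,
    value_col: str = "mean_ph",
    role_col: str = "role",
) -> tuple[pd.DataFrame, float, float]:
    """Z-normalise one replicate batch against its own wild-type wells.

    Returns ``(frame_with_z, wt_mean, wt_sd)``.  The wild-type statistics are
    computed from the batch's wild-type wells only (sample SD, ddof=1), so the
    wild-type Z population of any batch has mean 0 and SD 1 by construction.
    """
    wt = batch.loc[batch[role_col] == "wild_type", value_col].dropna()
    if len(wt) < 2:
        raise BatchError(
            f"batch needs >=2 wild-type wells for Z normalisation, found {len(wt)}"
        )
    wt_mean = float(wt.mean())
    wt_sd = float(wt.std(ddof=1))
    if not wt_sd > 0:
        raise BatchError("wild-type wells have zero spread; cannot normalise")
    out = batch.copy()
    out["z"] = (out[value_col] - wt_mean) / wt_sd
    return out, wt_mean, wt_sd


def select_candidates(
    z1,
    z2,
    z_primary: float = 2.0,
    z_secondary: float = 1.0,
    require_same_sign: bool = True,
):
    """Duplicate-screen candidate rule.

    True iff one replicate reaches |Z| >= z_primary while the other reaches
    |Z| >= z_secondary, and (by default) both deviate in the same direction.
    Symmetric in its two arguments.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    a1, a2 = np.abs(z1), np.abs(z2)
    hit = ((a1 >= z_primary) & (a2 >= z_secondary)) | (
        (a2 >= z_primary) & (a1 >= z_secondary)
    )
    if require_same_sign:
        hit = hit & (np.sign(z1) == np.sign(z2))
    hit = hit & np.isfinite(z1) & np.isfinite(z2)
    if hit.ndim == 0:
        return bool(hit)
    return hit


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample t-test (pooled variance by default).

    Degenerate zero-variance inputs are resolved deterministically: equal
    means give p = 1, unequal means p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t-test needs >=2 finite values per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return (np.inf if x[0] > y[0] else -np.inf), 0.0
    with warnings.catch_warnings():
        # near-identical samples (e.g. after trimming) are legitimate inputs
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def confirm_hits(
    strain_id: str,
    mutant_z,
    wt_z,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> HitCall:
    """Confirmatory t-test of a strain's rescreening Z-values vs the wild-type pool.

    Strains with fewer than 3 usable replicates are reported with status
    ``"nd"`` (not determined).  Otherwise status is ``"confirmed"`` when
    p < alpha, else ``"candidate"`` (selected but unconfirmed).
    """
    mz = np.asarray(mutant_z, dtype=float)
    mz = mz[np.isfinite(mz)]
    wz = np.asarray(wt_z, dtype=float)
    wz = wz[np.isfinite(wz)]
    if len(mz) < 3:
        return HitCall(
            strain_id=strain_id, direction=None, p_value=float("nan"),
            mean_z=float(mz.mean()) if len(mz) else float("nan"),
            n_replicates=len(mz), status="nd",
        )
    t, p = two_sample_t(mz, wz, equal_var=equal_var)
    mean_z = float(mz.mean())
    direction = "high" if mean_z > float(wz.mean()) else "low"
    return HitCall(
        strain_id=strain_id, direction=direction, p_value=p, mean_z=mean_z,
        n_replicates=len(mz), status="confirmed" if p < alpha else "candidate",
    )


def trim_extremes(values) -> np.ndarray:
    """Drop exactly one minimum and one maximum value (stable on ties)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValidationError("need >=3 values to trim extremes")
    order = np.argsort(values, kind="stable")
    keep = np.sort(order[1:-1])
    return values[keep]


def jackknife_retest(
    call: HitCall,
    mutant_z,
    wt_z,
    alpha: float = 0.01,
    alpha_jk: float = 0.1,
    equal_var: bool = True,
) -> HitCall:
    """Re-test a call after discarding the strain's lowest and highest replicate.

    Calls whose trimmed P-value exceeds ``alpha_jk`` are demoted to
    ``"discarded_jackknife"``; the trim never promotes a non-hit.  Strains
    with fewer than 4 replicates are left untouched with a warning.
    """
    mz = np.asarray(mutant_z, dtype=float)
    mz = mz[np.isfinite(mz)]
    if len(mz) < 4:
        warnings.warn(
            f"{call.strain_id}: <4 replicates, Jackknife skipped; original "
            "call stands",
            stacklevel=2,
        )
        return call
    trimmed = trim_extremes(mz)
    _, p_jk = two_sample_t(trimmed, wt_z, equal_var=equal_var)
    status = call.status
    if status == "confirmed" and p_jk > alpha_jk:
        status = "discarded_jackknife"
    return replace(call, status=status, p_jackknife=p_jk)


def condition_profile(
    strain_id: str,
    mutant_by_condition: Mapping[str, object],
    parent_by_condition: Mapping[str, object],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict[str, HitCall]:
    """Per-condition deviation calls of one strain against the parent strain.

    Each condition is tested independently (two-tailed t-test of the strain's
    replicate values against the parent's).  Conditions missing from either
    side, or with fewer than 3 mutant replicates, are omitted with a warning.
    """
    out: dict[str, HitCall] = {}
    for cond, parent_vals in parent_by_condition.items():
        if cond not in mutant_by_condition:
            warnings.warn(
                f"{strain_id}: no data for condition {cond!r}; omitted",
                stacklevel=2,
            )
            continue
        mv = np.asarray(mutant_by_condition[cond], dtype=float)
        mv = mv[np.isfinite(mv)]
        pv = np.asarray(parent_vals, dtype=float)
        pv = pv[np.isfinite(pv)]
        if len(mv) < 3:
            warnings.warn(
                f"{strain_id}: <3 replicates in condition {cond!r}; omitted",
                stacklevel=2,
            )
            continue
        _, p = two_sample_t(mv, pv, equal_var=equal_var)
        diff = float(mv.mean() - pv.mean())
        out[cond] = HitCall(
            strain_id=strain_id,
            direction="high" if diff > 0 else "low",
            p_value=p, mean_z=diff, n_replicates=len(mv),
            status="confirmed" if p < alpha else "not_candidate",
        )
    return out


def cross_condition_sets(
    profiles: Mapping[str, Mapping[str, HitCall]],
    conditions=None,
    acid_condition: str = "glc_pH3.0",
    alkaline_condition: str = "glc_pH7.5",
) -> dict[str, set[str]]:
    """Venn-style cross-condition summaries of per-condition calls.

    * ``consistently_low`` / ``consistently_high``: significant in the same
      direction in *all* listed conditions;
    * ``ph_fragile``: high at the alkaline external pH but low at the acid
      one — strains that have lost pH_c control with respect to pH_ex.
    """
    if conditions is None:
        conditions = sorted({c for calls in profiles.values() for c in calls})

    def sig(call: HitCall | None, direction: str) -> bool:
        return (call is not None and call.status == "confirmed"
                and call.direction == direction)

    out = {"consistently_low": set(), "consistently_high": set(),
           "ph_fragile": set()}
    for strain, calls in profiles.items():
        if conditions and all(sig(calls.get(c), "low") for c in conditions):
            out["consistently_low"].add(strain)
        if conditions and all(sig(calls.get(c), "high") for c in conditions):
            out["consistently_high"].add(strain)
        if sig(calls.get(alkaline_condition), "high") and sig(
            calls.get(acid_condition), "low"
        ):
            out["ph_fragile"].add(strain)
    return out


def false_negative_rate(
    truth: Mapping[str, str],
    selected: Mapping[str, bool],
) -> dict[str, float]:
    """Fraction of true hits per direction missed by the candidate rule.

    ``truth`` maps strain -> "low"/"high"; ``selected`` maps strain -> whether
    the duplicate-screen rule picked it up.  Directions with no true members
    report NaN.
    """
    out = {}
    for direction in ("low", "high"):
        ids = [s for s, d in truth.items() if d == direction]
        if not ids:
            out[f"fn_{direction}"] = float("nan")
            continue
        hit = sum(bool(selected.get(s, False)) for s in ids)
        out[f"fn_{direction}"] = 1.0 - hit / len(ids)
    return out
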