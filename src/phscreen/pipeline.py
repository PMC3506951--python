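"""Stage drivers that chain the modules into the screen workflow.

The drivers consume :class:`~phscreen.plate_io.PlateTimeCourse` lists whose
plate ids encode the replicate batch as ``{batch}-{plate}``, e.g.
``S1-P001`` (first primary screening replicate) or ``R4-P002`` (fourth
rescreen replicate).  Batches whose label starts with ``S`` form the
primary duplicate screen used for candidate selection; ``R`` batches are
the confirmatory rescreens.  Everything downstream of plate parsing works
on plain DataFrames so results can be written to and re-read from CSV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import calibration, growth, ph_growth_model, screening
from .errors import ValidationError

__all__ = [
    "batch_of", "summarize_screen", "screen_calls", "run_screen",
    "growth_ph_table", "fit_growth_law", "build_profiles", "classify_table",
    "candidate_selection_table",
]


def batch_of(plate_id: str) -> str:
    """Replicate-batch label of a plate id (the part before the first '-')."""
    return plate_id.split("-", 1)[0]


def summarize_screen(
    plates,
    curve,
    measure_window: tuple[float, float] = (3.5, 4.5),
) -> pd.DataFrame:
    """Per-well mean pH over the measurement window, one row per non-blank well.

    Columns: batch, plate_id, well, strain_id, role, condition, mean_ph.
    """
    rows = []
    for plate in plates:
        ph = calibration.plate_to_ph(plate, curve)
        lo, hi = measure_window
        sel = [t for t in ph.columns if lo <= t <= hi]
        if not sel:
            raise ValidationError(
                f"plate {plate.plate_id}: no timepoints in the measurement "
                f"window {measure_window}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = ph[sel].mean(axis=1, skipna=True)
        for w in plate.wells:
            if w.role == "blank":
                continue
            rows.append({
                "batch": batch_of(plate.plate_id),
                "plate_id": plate.plate_id,
                "well": w.well,
                "strain_id": w.strain_id,
                "role": w.role,
                "condition": w.condition,
                "mean_ph": float(means.loc[w.well]),
            })
    return pd.DataFrame(rows)


def _add_z(summary: pd.DataFrame) -> pd.DataFrame:
    parts = []
    for _, grp in summary.groupby("batch", sort=True):
        with_z, _, _ = screening.replicate_z_values(grp)
        parts.append(with_z)
    return pd.concat(parts, ignore_index=True)


def candidate_selection_table(
    summary_z: pd.DataFrame,
    z_primary: float = 2.0,
    z_secondary: float = 1.0,
    require_same_sign: bool = True,
) -> pd.DataFrame:
    """Apply the duplicate-screen candidate rule to the primary (S) batches."""
    primary = sorted(
        b for b in summary_z["batch"].unique() if str(b).startswith("S")
    )
    if len(primary) < 2:
        raise ValidationError(
            f"need >=2 primary screening batches (labels 'S*'), found {primary}"
        )
    s1, s2 = primary[:2]
    muts = summary_z[summary_z["role"].isin(["mutant", "slow_grower"])]
    z_by_batch = muts.pivot_table(index="strain_id", columns="batch",
                                  values="z", aggfunc="mean")
    out = pd.DataFrame({
        "strain_id": z_by_batch.index,
        "z_screen_1": z_by_batch.get(s1, pd.Series(index=z_by_batch.index,
                                                   dtype=float)).to_numpy(),
        "z_screen_2": z_by_batch.get(s2, pd.Series(index=z_by_batch.index,
                                                   dtype=float)).to_numpy(),
    }).reset_index(drop=True)
    out["candidate"] = screening.select_candidates(
        out["z_screen_1"].to_numpy(), out["z_screen_2"].to_numpy(),
        z_primary=z_primary, z_secondary=z_secondary,
        require_same_sign=require_same_sign,
    )
    return out


def screen_calls(
    summary_z: pd.DataFrame,
    z_primary: float = 2.0,
    z_secondary: float = 1.0,
    alpha_confirm: float = 0.01,
    alpha_jackknife: float = 0.1,
    require_same_sign: bool = True,
    jackknife: str = "slow_grower",
) -> pd.DataFrame:
    """Full hit-calling on a Z-annotated screen summary.

    Candidates come from the two primary batches; candidates and all
    slow-grower-array strains are confirmed against the rescreen wild-type
    Z pool; the Jackknife re-test is applied per ``jackknife`` policy
    ("slow_grower" — the separately arrayed strains only, "all", "none").
    """
    if jackknife not in ("slow_grower", "all", "none"):
        raise ValidationError(f"unknown jackknife policy {jackknife!r}")
    cand = candidate_selection_table(
        summary_z, z_primary=z_primary, z_secondary=z_secondary,
        require_same_sign=require_same_sign,
    ).set_index("strain_id")
    rescreen = summary_z[summary_z["batch"].astype(str).str.startswith("R")]
    if rescreen.empty:
        raise ValidationError("no rescreen batches (labels 'R*') present")
    wt_z = rescreen.loc[rescreen["role"] == "wild_type", "z"].to_numpy()
    muts = rescreen[rescreen["role"].isin(["mutant", "slow_grower"])]
    rows = []
    for strain_id, grp in muts.groupby("strain_id", sort=True):
        role = grp["role"].iloc[0]
        mz = grp["z"].to_numpy()
        is_candidate = bool(cand["candidate"].get(strain_id, False))
        tested = is_candidate or role == "slow_grower"
        if not tested:
            rows.append({
                "strain_id": strain_id, "role": role,
                "z_screen_1": cand["z_screen_1"].get(strain_id, np.nan),
                "z_screen_2": cand["z_screen_2"].get(strain_id, np.nan),
                "candidate": is_candidate, "n_rescreen": len(mz),
                "mean_z": float(np.nanmean(mz)) if len(mz) else np.nan,
                "mean_ph": float(grp["mean_ph"].mean()),
                "direction": "", "p_value": np.nan, "p_jackknife": np.nan,
                "status": "not_candidate",
            })
            continue
        call = screening.confirm_hits(strain_id, mz, wt_z, alpha=alpha_confirm)
        if call.status != "nd" and (
            jackknife == "all" or (jackknife == "slow_grower"
                                   and role == "slow_grower")
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                call = screening.jackknife_retest(
                    call, mz, wt_z, alpha=alpha_confirm, alpha_jk=alpha_jackknife,
                )
        rows.append({
            "strain_id": strain_id, "role": role,
            "z_screen_1": cand["z_screen_1"].get(strain_id, np.nan),
            "z_screen_2": cand["z_screen_2"].get(strain_id, np.nan),
            "candidate": is_candidate, "n_rescreen": call.n_replicates,
            "mean_z": call.mean_z, "mean_ph": float(grp["mean_ph"].mean()),
            "direction": call.direction or "",
            "p_value": call.p_value,
            "p_jackknife": (np.nan if call.p_jackknife is None
                            else call.p_jackknife),
            "status": call.status,
        })
    return pd.DataFrame(rows)


def run_screen(
    plates,
    curve,
    measure_window: tuple[float, float] = (3.5, 4.5),
    **call_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plates -> (per-well Z summary, per-strain hit table)."""
    summary = _add_z(summarize_screen(plates, curve, measure_window))
    calls = screen_calls(summary, **call_kwargs)
    return summary, calls


def growth_ph_table(
    plates,
    curve,
    slope_window: int = 6,
) -> pd.DataFrame:
    """Paired per-window (mu, pH) observations for every non-blank well.

    mu is the sliding-window slope of ln(OD_cor); pH is the nan-mean of the
    calibrated per-timepoint pH over the same window, so both sit at the
    window-centre time.  Columns: batch, plate_id, well, strain_id, role,
    time, mu, ph.
    """
    frames = []
    for plate in plates:
        ph = calibration.plate_to_ph(plate, curve)
        keep = ~plate.role_mask("blank")
        od_cor = growth.correct_od(plate.od_raw[keep])
        wells = [w for w, k in zip(plate.wells, keep) if k]
        for i, w in enumerate(wells):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                centers, mu = growth.growth_rate_series(
                    plate.times, od_cor[i], window=slope_window
                )
            if len(mu) == 0:
                continue
            _, ph_means = growth.window_means(
                plate.times, ph.loc[w.well].to_numpy(), window=slope_window
            )
            frames.append(pd.DataFrame({
                "batch": batch_of(plate.plate_id),
                "plate_id": plate.plate_id,
                "well": w.well,
                "strain_id": w.strain_id,
                "role": w.role,
                "time": centers,
                "mu": mu,
                "ph": ph_means,
            }))
    if not frames:
        raise ValidationError("no usable growth curves in the input plates")
    return pd.concat(frames, ignore_index=True)


def fit_growth_law(
    table: pd.DataFrame,
    t_exclusion: float = 1.5,
) -> ph_growth_model.PhGrowthFit:
    """Fit the pH->mu law on the wild-type rows of a growth/pH table."""
    wt = table[table["role"] == "wild_type"]
    if wt.empty:
        raise ValidationError("no wild-type rows to fit the growth law on")
    return ph_growth_model.fit_ph_growth(
        wt["ph"].to_numpy(), wt["mu"].to_numpy(), times=wt["time"].to_numpy(),
        t_exclusion=t_exclusion,
    )


def build_profiles(
    table: pd.DataFrame,
    fit,
    window: tuple[float, float] = (4.0, 9.0),
):
    """Divergence profiles: per-curve for wild type, replicate-averaged per strain.

    Returns ``(wt_profiles, strain_profiles)``.  Wild-type reference profiles
    are individual replicate curves (one per well); each mutant /
    slow-grower strain gets one profile whose z_t is the nan-mean across its
    replicate wells.
    """
    grid = np.sort(table["time"].unique())
    wt_curves = []
    wt_keys = []
    for (plate_id, well), grp in table[table["role"] == "wild_type"].groupby(
        ["plate_id", "well"], sort=True
    ):
        grp = grp.sort_values("time")
        if len(grp) != len(grid) or not np.allclose(grp["time"], grid):
            raise ValidationError("wild-type curves disagree on the time grid")
        wt_curves.append((grid, grp["mu"].to_numpy(), grp["ph"].to_numpy()))
        wt_keys.append(f"WT@{plate_id}:{well}")
    stats = ph_growth_model.wt_residual_stats(wt_curves, fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt_profiles = [
            ph_growth_model.divergence_profile(
                key, grid, mu, ph, fit, stats, window=window
            )
            for key, (_, mu, ph) in zip(wt_keys, wt_curves)
        ]
        strain_profiles = []
        for strain_id, grp in table[
            table["role"].isin(["mutant", "slow_grower"])
        ].groupby("strain_id", sort=True):
            z_rows = []
            for (_, well), g in grp.groupby(["plate_id", "well"], sort=True):
                g = g.sort_values("time")
                if len(g) != len(grid) or not np.allclose(g["time"], grid):
                    raise ValidationError(
                        f"{strain_id}: curve disagrees with the time grid"
                    )
                prof = ph_growth_model.divergence_profile(
                    strain_id, grid, g["mu"].to_numpy(), g["ph"].to_numpy(),
                    fit, stats, window=window,
                )
                z_rows.append(prof.z_t)
            z_mean = np.nanmean(np.vstack(z_rows), axis=0)
            strain_profiles.append(ph_growth_model.DivergenceProfile(
                strain_id=strain_id, times=prof.times, z_t=z_mean,
                mean_z=float(np.nanmean(z_mean)),
            ))
    return wt_profiles, strain_profiles


def classify_table(
    table: pd.DataFrame,
    fit,
    window: tuple[float, float] = (4.0, 9.0),
    alpha: float = 0.01,
    correction: str = "wildtype_floor",
) -> tuple[pd.DataFrame, list, list]:
    """Classify every mutant strain of a growth/pH table against the law.

    Returns ``(calls_frame, strain_profiles, wt_profiles)``.
    """
    wt_profiles, strain_profiles = build_profiles(table, fit, window=window)
    calls = ph_growth_model.classify_cohort(
        strain_profiles, wt_profiles, alpha=alpha, correction=correction,
    )
    frame = pd.DataFrame([{
        "strain_id": c.strain_id,
        "category": c.category,
        "mean_z": c.mean_z,
        "p_raw": c.p_raw,
        "p_corrected": c.p_corrected,
    } for c in calls])
    return frame, strain_profiles, wt_profiles
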