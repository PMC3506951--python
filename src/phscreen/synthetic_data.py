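"""Seeded synthetic screens with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without the physical deletion collection:

* wild-type cytosolic pH 7.08 with an SD of 0.05 across biological
  replicates; mutant offsets confined to [-0.3, +0.5] pH units;
* a phenomenological pH trajectory: neutral plateau in early exponential
  phase, a gradual ~0.3-unit decline through late exponential phase, and a
  fall to pH 5.5 once glucose is depleted (default 8 h);
* growth coupled to pH through mu = 10**((pH + a)/b) with a = -7.24,
  b = 0.73, integrated on a 10-minute grid over 16 h — except for planted
  "decoupled" strains that grow at a fixed rate regardless of pH, and
  planted slow strains whose rate is a fixed fraction of the coupled rate;
* a ratiometric fluorescence readout generated from the calibration sigmoid
  and scaled by biomass, with multiplicative channel noise and an additive
  background emitted alone by blank wells; raw OD is produced by inverting
  the OD-linearisation polynomial and adding read noise.

The screen design mirrors the real workflow: two primary screening
replicates plus six confirmatory rescreen replicates of the same plate
layout, with a truth table listing every planted strain.  All outputs are
bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationStandard
from .errors import ConfigError
from .growth import invert_correct_od
from .plate_io import PlateTimeCourse, WellRecord

__all__ = [
    "PlantedStrain", "SyntheticConfig", "default_calibration",
    "simulate_ph_trajectory", "simulate_growth", "simulate_fluorescence",
    "simulate_blank", "simulate_plate", "simulate_screen",
    "make_standards", "synthetic_annotation",
]

OFFSET_RANGE = (-0.3, 0.5)  # observed span of single-deletion pH_c offsets


def default_calibration() -> CalibrationCurve:
    """Typical in-situ pHluorin excitation-ratio response."""
    return CalibrationCurve(r_min=0.3, r_max=3.0, ph_mid=6.9, slope_k=1.1,
                            valid_range=(5.0, 8.5), rmse=0.0)


@dataclass(frozen=True)
class PlantedStrain:
    """Ground-truth specification of one planted mutant."""

    strain_id: str
    ph_offset: float = 0.0
    coupling: str = "coupled"          # "coupled" | "decoupled"
    mu_fixed: float | None = None      # h^-1, required for decoupled strains
    growth_scale: float = 1.0          # <1 plants a slower-than-law strain
    role: str = "mutant"               # "mutant" | "slow_grower"

    def __post_init__(self) -> None:
        lo, hi = OFFSET_RANGE
        if not lo <= self.ph_offset <= hi:
            raise ConfigError(
                f"{self.strain_id}: pH offset {self.ph_offset} outside "
                f"[{lo}, {hi}]"
            )
        if self.coupling not in ("coupled", "decoupled"):
            raise ConfigError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "decoupled" and self.mu_fixed is None:
            raise ConfigError(f"{self.strain_id}: decoupled needs mu_fixed")
        if self.role not in ("mutant", "slow_grower"):
            raise ConfigError(f"{self.strain_id}: invalid role {self.role!r}")

    @property
    def true_category(self) -> str:
        if self.coupling == "decoupled":
            return "III"
        if self.growth_scale < 1.0:
            return "II"
        return "I"

    @property
    def true_direction(self) -> str:
        if self.ph_offset < 0:
            return "low"
        if self.ph_offset > 0:
            return "high"
        return "none"


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic screen."""

    seed: int = 0
    n_plates: int = 1
    wells_per_plate: int = 96
    n_blank_per_plate: int = 2
    n_wt_per_plate: int = 19   # ~20% wild-type wells, the screened array's ratio
    n_screen_reps: int = 2            # primary duplicate screen
    n_rescreen_reps: int = 6          # confirmatory replicates
    wt_ph_mean: float = 7.08          # parent pH_c
    wt_ph_sd: float = 0.05            # biological replicate SD
    a_true: float = -7.24             # growth-law offset
    b_true: float = 0.73              # pH units per decade of mu
    sample_dt_min: float = 10.0       # sampling interval
    duration_h: float = 16.0
    od0: float = 0.05                 # corrected OD at inoculation
    decline_start_h: float = 5.0      # late-exponential pH decline onset
    decline_drop: float = 0.3         # pH units lost before depletion
    depletion_h: float = 8.0          # glucose depletion time
    fall_to_ph: float = 5.5           # post-depletion cytosolic pH
    fall_duration_h: float = 1.0
    ph_noise_sd: float = 0.02         # per-timepoint pH jitter
    od_sd: float = 0.002              # additive OD read noise
    fluor_cv: float = 0.01            # multiplicative channel noise
    fluor_gain: float = 2000.0        # AU per corrected-OD unit per channel
    background: float = 50.0          # AU per channel
    background_sd: float = 1.0
    condition: str = "glc_pH5.0"
    calibration: CalibrationCurve = field(default_factory=default_calibration)
    planted: list[PlantedStrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.wells_per_plate < self.n_blank_per_plate + self.n_wt_per_plate + 1:
            raise ConfigError("plate layout leaves no room for mutant wells")
        if self.n_wt_per_plate < 2:
            raise ConfigError("need >=2 wild-type wells per plate for Z-values")
        if not self.duration_h > 0 or not self.sample_dt_min > 0:
            raise ConfigError("duration and sampling interval must be positive")
        if self.mutants_per_plate * self.n_plates < len(self.planted):
            raise ConfigError(
                f"{len(self.planted)} planted strains exceed the "
                f"{self.mutants_per_plate * self.n_plates} mutant wells available"
            )
        ids = [p.strain_id for p in self.planted]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate planted strain ids")

    @property
    def mutants_per_plate(self) -> int:
        return self.wells_per_plate - self.n_blank_per_plate - self.n_wt_per_plate

    def times(self) -> np.ndarray:
        n = int(round(self.duration_h * 60.0 / self.sample_dt_min)) + 1
        return np.arange(n) * self.sample_dt_min / 60.0


def simulate_ph_trajectory(
    config: SyntheticConfig,
    rng: np.random.Generator,
    offset: float = 0.0,
    bio_offset: float | None = None,
) -> np.ndarray:
    """One well's cytosolic-pH time series on the sample grid.

    Piecewise shape: plateau at ``wt_ph_mean + offset`` (plus a biological
    replicate offset drawn from N(0, wt_ph_sd) unless given), a linear
    decline of ``decline_drop`` units from ``decline_start_h`` to
    ``depletion_h``, a linear fall to ``fall_to_ph`` over
    ``fall_duration_h``, then a hold; per-timepoint Gaussian jitter of
    ``ph_noise_sd`` on top.  Deterministic given the generator state.
    """
    t = config.times()
    if bio_offset is None:
        bio_offset = float(rng.normal(0.0, config.wt_ph_sd)) if config.wt_ph_sd else 0.0
    plateau = config.wt_ph_mean + offset + bio_offset
    low = plateau - config.decline_drop
    ph = np.full_like(t, plateau)
    decline = (t >= config.decline_start_h) & (t < config.depletion_h)
    span = config.depletion_h - config.decline_start_h
    if span > 0:
        ph[decline] = plateau - config.decline_drop * (
            (t[decline] - config.decline_start_h) / span
        )
    fall_end = config.depletion_h + config.fall_duration_h
    falling = (t >= config.depletion_h) & (t < fall_end)
    if config.fall_duration_h > 0:
        frac = (t[falling] - config.depletion_h) / config.fall_duration_h
        ph[falling] = low + (config.fall_to_ph - low) * frac
    ph[t >= fall_end] = config.fall_to_ph
    if config.ph_noise_sd:
        ph = ph + rng.normal(0.0, config.ph_noise_sd, size=len(t))
    return ph


def _mu_of_ph(config: SyntheticConfig, ph: np.ndarray) -> np.ndarray:
    return 10.0 ** ((ph + config.a_true) / config.b_true)


def simulate_growth(
    config: SyntheticConfig,
    times: np.ndarray,
    ph: np.ndarray,
    coupling: str = "coupled",
    mu_fixed: float | None = None,
    growth_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate growth along a pH trajectory; returns (od_true, od_raw).

    Coupled wells grow at ``growth_scale * 10**((pH + a)/b)``; decoupled
    wells at ``mu_fixed`` while pH stays above the depletion floor (growth
    stops once the cytosol has collapsed to ``fall_to_ph``).  ``od_raw`` is
    the raw plate-reader reading: the inverse of the OD-linearisation
    polynomial plus additive Gaussian read noise.
    """
    times = np.asarray(times, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if coupling == "decoupled":
        if mu_fixed is None:
            raise ConfigError("decoupled growth needs mu_fixed")
        mu = np.where(ph > config.fall_to_ph + 0.05, mu_fixed, 0.0)
    elif coupling == "coupled":
        mu = growth_scale * _mu_of_ph(config, ph)
    else:
        raise ConfigError(f"unknown coupling {coupling!r}")
    dt = np.diff(times)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (mu[1:] + mu[:-1]) * dt)])
    od_true = config.od0 * np.exp(integral)
    od_raw = invert_correct_od(od_true)
    if rng is not None and config.od_sd:
        od_raw = od_raw + rng.normal(0.0, config.od_sd, size=len(times))
    return od_true, od_raw


def simulate_fluorescence(
    config: SyntheticConfig,
    ph: np.ndarray,
    od_true: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model of the two-channel ratiometric readout.

    The channel signals carry the calibration-sigmoid ratio (F390/F470)
    scaled by biomass; both channels get multiplicative noise and the common
    additive background.  pH outside the calibration range is clamped into
    the open interval (the reported ratio saturates, as it would in vivo).
    """
    curve = config.calibration
    lo, hi = curve.valid_range
    eps = 1e-9
    ph_c = np.clip(np.asarray(ph, dtype=float), lo + eps, hi - eps)
    ratio = curve.ratio(ph_c)
    intensity = config.fluor_gain * np.asarray(od_true, dtype=float)
    f470 = intensity.copy()
    f390 = ratio * intensity
    n = len(ph_c)
    if rng is not None:
        if config.fluor_cv:
            f390 = f390 * (1.0 + rng.normal(0.0, config.fluor_cv, size=n))
            f470 = f470 * (1.0 + rng.normal(0.0, config.fluor_cv, size=n))
        f390 = f390 + config.background + rng.normal(0.0, config.background_sd, n)
        f470 = f470 + config.background + rng.normal(0.0, config.background_sd, n)
    else:
        f390 = f390 + config.background
        f470 = f470 + config.background
    return f390, f470


def simulate_blank(
    config: SyntheticConfig,
    n_times: int,
    rng: np.random.Generator,
):
    """Blank-well readings: background only, plus read noise."""
    od_raw = rng.normal(0.0, config.od_sd, n_times) if config.od_sd else np.zeros(n_times)
    f390 = config.background + rng.normal(0.0, config.background_sd, n_times)
    f470 = config.background + rng.normal(0.0, config.background_sd, n_times)
    return od_raw, f390, f470


def _well_names(n: int) -> list[str]:
    cols = 12 if n <= 96 else 24
    rows = "ABCDEFGHIJKLMNOP"
    names = [f"{rows[i // cols]}{i % cols + 1:02d}" for i in range(n)]
    if n > len(rows) * cols:
        raise ConfigError(f"cannot lay out {n} wells on one plate")
    return names


def simulate_plate(
    config: SyntheticConfig,
    rng: np.random.Generator,
    layout,
    plate_id: str,
) -> PlateTimeCourse:
    """Simulate one plate from a layout of (well, strain_id, role, planted)."""
    times = config.times()
    n_t = len(times)
    wells, od_rows, f390_rows, f470_rows = [], [], [], []
    for well, strain_id, role, planted in layout:
        wells.append(WellRecord(
            plate_id=plate_id, well=well, strain_id=strain_id, role=role,
            condition=config.condition,
        ))
        if role == "blank":
            od_raw, f390, f470 = simulate_blank(config, n_t, rng)
        else:
            offset = planted.ph_offset if planted is not None else 0.0
            ph = simulate_ph_trajectory(config, rng, offset=offset)
            if planted is not None:
                od_true, od_raw = simulate_growth(
                    config, times, ph, coupling=planted.coupling,
                    mu_fixed=planted.mu_fixed,
                    growth_scale=planted.growth_scale, rng=rng,
                )
            else:
                od_true, od_raw = simulate_growth(config, times, ph, rng=rng)
            f390, f470 = simulate_fluorescence(config, ph, od_true, rng)
        od_rows.append(od_raw)
        f390_rows.append(f390)
        f470_rows.append(f470)
    return PlateTimeCourse(
        plate_id=plate_id, condition=config.condition, wells=wells,
        times=times, od_raw=np.vstack(od_rows), f390=np.vstack(f390_rows),
        f470=np.vstack(f470_rows),
    )


def _build_layouts(config: SyntheticConfig):
    """Fixed array layout shared by every replicate (a deletion-array plate set)."""
    planted_by_id = {p.strain_id: p for p in config.planted}
    n_mut = config.mutants_per_plate * config.n_plates
    roster = [p.strain_id for p in config.planted]
    width = max(4, len(str(n_mut)))
    roster += [f"ynull{i:0{width}d}" for i in range(n_mut - len(roster))]
    names = _well_names(config.wells_per_plate)
    layouts = []
    cursor = 0
    for _ in range(config.n_plates):
        layout = []
        for j, well in enumerate(names):
            if j < config.n_blank_per_plate:
                layout.append((well, None, "blank", None))
            elif j < config.n_blank_per_plate + config.n_wt_per_plate:
                layout.append((well, "WT", "wild_type", None))
            else:
                sid = roster[cursor]
                cursor += 1
                planted = planted_by_id.get(sid)
                role = planted.role if planted is not None else "mutant"
                layout.append((well, sid, role, planted))
        layouts.append(layout)
    return layouts, roster


def simulate_screen(
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[list[PlateTimeCourse], pd.DataFrame]:
    """Full screen: primary duplicate + confirmatory rescreen replicates.

    Plate ids follow ``{phase}{replicate}-P{plate:03d}`` with phase ``S``
    for the primary screening replicates and ``R`` for the rescreens; the
    replicate label (the part before ``-``) identifies the Z-normalisation
    batch.  Returns the plates and a truth table with one row per strain.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layouts, roster = _build_layouts(config)
    plates = []
    for phase, reps in (("S", config.n_screen_reps), ("R", config.n_rescreen_reps)):
        for rep in range(1, reps + 1):
            for p, layout in enumerate(layouts, start=1):
                plates.append(simulate_plate(
                    config, rng, layout, plate_id=f"{phase}{rep}-P{p:03d}",
                ))
    planted_by_id = {p.strain_id: p for p in config.planted}
    rows = []
    for sid in roster:
        p = planted_by_id.get(sid)
        rows.append({
            "strain_id": sid,
            "true_ph_offset": p.ph_offset if p else 0.0,
            "true_direction": p.true_direction if p else "none",
            "true_category": p.true_category if p else "I",
        })
    truth = pd.DataFrame(rows)
    return plates, truth


def make_standards(
    config: SyntheticConfig,
    n: int = 9,
    ph_lo: float = 5.2,
    ph_hi: float = 8.3,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[CalibrationStandard]:
    """Buffer standards sampled from the generator's true calibration curve."""
    phs = np.linspace(ph_lo, ph_hi, n)
    ratios = config.calibration.ratio(phs)
    if noise_cv and rng is not None:
        ratios = ratios * (1.0 + rng.normal(0.0, noise_cv, size=n))
    return [CalibrationStandard(ph=float(p), ratio=float(r))
            for p, r in zip(phs, ratios)]


def synthetic_annotation(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    n_random_terms: int = 5,
    random_term_frac: float = 0.1,
) -> dict[str, set[str]]:
    """Toy term -> strain map for exercising the enrichment stage.

    Planted strains share direction terms (``ph_low`` / ``ph_high``); every
    strain is additionally sprinkled into unrelated random terms at a fixed
    rate, giving null terms with fold ~= 1.
    """
    out: dict[str, set[str]] = {}
    low = set(truth.loc[truth["true_direction"] == "low", "strain_id"])
    high = set(truth.loc[truth["true_direction"] == "high", "strain_id"])
    if low:
        out["ph_low"] = low
    if high:
        out["ph_high"] = high
    strains = list(truth["strain_id"])
    for i in range(n_random_terms):
        pick = rng.random(len(strains)) < random_term_frac
        members = {s for s, keep in zip(strains, pick) if keep}
        if len(members) >= 2:
            out[f"random_term_{i + 1}"] = members
    return out
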