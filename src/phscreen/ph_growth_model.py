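"""The exponential pH_c -> growth-rate law and divergence classification.

Wild-type specific growth rate depends exponentially on cytosolic pH:

    mu = 10 ** ((pH_c + a) / b)

equivalently, log10(mu) is affine in pH_c with slope 1/b and intercept a/b.
The parameters are estimated by ordinary least squares of log10(mu) on pH_c
over paired per-timepoint (pH_c, mu) observations of wild-type cultures,
excluding the first ~1.5 h after inoculation (pH_c recovers to neutral
before growth restarts, so those points sit off the law) and any mu <= 0.

Mutants are compared to the law through per-timepoint divergence Z-profiles:
the residual mu_obs(t) - mu_pred(pH_c(t)) is standardised by the mean and SD
of the same residual across wild-type replicate cultures at that timepoint.
A two-sample t-test of a strain's windowed Z-values (default t = 4-9 h)
against the pooled wild-type Z-values, multiplied by a correction factor
that renders every wild-type profile non-significant, assigns each strain to
one of three categories:

* I  — wild-type-like: on the law (pH_c deviations, if any, act through the law);
* II — slower than the law predicts (growth limited by something else);
* III — faster than the law predicts ("decoupled": growth escapes pH_c control).

Profiles are hierarchically clustered (Euclidean distance, complete linkage)
for presentation, with a Newick export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .errors import FitError, ValidationError
from .screening import two_sample_t

__all__ = [
    "PhGrowthFit", "fit_ph_growth", "predict_mu",
    "WtResidualStats", "wt_residual_stats",
    "DivergenceProfile", "divergence_profile",
    "CategoryCall", "wildtype_correction_factor", "classify_mutant",
    "classify_cohort", "ClusterResult", "cluster_profiles", "cut_clusters",
    "CATEGORY_WT", "CATEGORY_SLOW", "CATEGORY_DECOUPLED",
]

CATEGORY_WT = "I_wildtype_like"
CATEGORY_SLOW = "II_low_growth"
CATEGORY_DECOUPLED = "III_decoupled"


@dataclass
class PhGrowthFit:
    """Fitted parameters of mu = 10**((pH_c + a) / b)."""

    a: float                 # pH-unit offset; -a is the pH_c at which mu = 1/h
    b: float                 # pH units per decade of mu (b > 0)
    se_a: float
    se_b: float
    r2: float                # of the linear fit log10(mu) ~ pH_c
    n_points: int
    n_excluded: int = 0      # mu <= 0 or earlier than the exclusion time
    fit_window: tuple[float, float] | None = None


def fit_ph_growth(ph, mu, times=None, t_exclusion: float = 1.5) -> PhGrowthFit:
    """Least-squares fit of the growth law in log10(mu) space.

    Parameters
    ----------
    ph, mu
        Paired per-timepoint observations.
    times
        Optional observation times (hours); points earlier than
        ``t_exclusion`` are dropped (cells re-alkalinise before growth
        restarts, so early points sit off the law).
    """
    ph = np.asarray(ph, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if ph.shape != mu.shape:
        raise ValidationError("ph and mu must have identical shapes")
    mask = np.isfinite(ph) & np.isfinite(mu)
    if times is not None:
        times = np.asarray(times, dtype=float)
        mask &= times >= t_exclusion
    n_before = int(mask.sum())
    if n_before and not np.any(mu[mask] > 0):
        raise FitError("all growth rates are <= 0; nothing to fit")
    pos = mask & (mu > 0)
    n_excluded = n_before - int(pos.sum())
    x = ph[pos]
    y = np.log10(mu[pos])
    n = len(x)
    if n < 2:
        raise FitError(f"need >=2 usable (pH, mu) points, have {n}")
    if np.ptp(x) == 0:
        raise FitError("zero variance in pH_c; slope is unidentifiable")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    c, s = float(beta[0]), float(beta[1])
    if s <= 0:
        raise FitError(
            f"fitted slope {s:.4g} <= 0; growth must increase with pH_c "
            "for this law"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else max(0.0, min(1.0, 1.0 - rss / tss))
    if n > 2:
        sigma2 = rss / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        var_c, var_s = cov[0, 0], cov[1, 1]
        cov_cs = cov[0, 1]
        se_b = np.sqrt(var_s) / s ** 2
        # a = c / s; delta method with the full covariance
        var_a = (var_c / s ** 2 + (c ** 2 / s ** 4) * var_s
                 - 2.0 * (c / s ** 3) * cov_cs)
        se_a = float(np.sqrt(max(var_a, 0.0)))
    else:
        se_a = se_b = float("nan")
    window = None
    if times is not None:
        used = times[pos]
        window = (float(used.min()), float(used.max()))
    return PhGrowthFit(
        a=c / s, b=1.0 / s, se_a=se_a, se_b=float(se_b), r2=r2,
        n_points=n, n_excluded=n_excluded, fit_window=window,
    )


def predict_mu(fit, ph):
    """Growth rate (h^-1) predicted by the law; strictly increasing in pH_c.

    ``fit`` may be a :class:`PhGrowthFit` or an ``(a, b)`` pair.
    """
    if isinstance(fit, PhGrowthFit):
        a, b = fit.a, fit.b
    else:
        a, b = fit
    ph = np.asarray(ph, dtype=float)
    out = 10.0 ** ((ph + a) / b)
    if np.ndim(ph) == 0:
        return float(out)
    return out


@dataclass
class WtResidualStats:
    """Per-timepoint mean and SD of the wild-type divergence from the law."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_curves: int


def _check_grid(times_a, times_b, what: str) -> None:
    if len(times_a) != len(times_b) or not np.allclose(times_a, times_b):
        raise ValidationError(f"{what} must share the same time grid")


def wt_residual_stats(curves, fit) -> WtResidualStats:
    """Residual statistics over wild-type replicate curves.

    ``curves`` is a sequence of ``(times, mu, ph)`` triples sharing one time
    grid.  The residual is mu_obs - mu_pred(pH_c) at each timepoint; its
    across-replicate mean and sample SD anchor the divergence Z-values.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValidationError("need >=2 wild-type curves for residual statistics")
    t0 = np.asarray(curves[0][0], dtype=float)
    resid = []
    for times, mu, ph in curves:
        times = np.asarray(times, dtype=float)
        _check_grid(t0, times, "wild-type curves")
        resid.append(np.asarray(mu, float) - predict_mu(fit, np.asarray(ph, float)))
    resid = np.vstack(resid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(resid, axis=0)
        sd = np.nanstd(resid, axis=0, ddof=1)
    return WtResidualStats(times=t0, mean=mean, sd=sd, n_curves=len(curves))


@dataclass
class DivergenceProfile:
    """Windowed per-timepoint Z of a strain's growth-rate residual."""

    strain_id: str
    times: np.ndarray
    z_t: np.ndarray
    mean_z: float


def divergence_profile(
    strain_id: str,
    times,
    mu,
    ph,
    fit,
    wt_stats: WtResidualStats,
    window: tuple[float, float] = (4.0, 9.0),
) -> DivergenceProfile:
    """Standardise a strain's residual trajectory against the wild-type cohort.

    z_t = (r_t - wt_mean_t) / wt_sd_t with r_t = mu_obs(t) - mu_pred(pH_c(t)),
    restricted to the classification window (inclusive).  Timepoints where
    the wild-type SD is zero are NaN-masked with a warning.
    """
    times = np.asarray(times, dtype=float)
    _check_grid(wt_stats.times, times, "strain and wild-type statistics")
    mu = np.asarray(mu, dtype=float)
    ph = np.asarray(ph, dtype=float)
    resid = mu - predict_mu(fit, ph)
    sd = wt_stats.sd
    zero_sd = np.isfinite(sd) & (sd == 0)
    if zero_sd.any():
        warnings.warn(
            f"{strain_id}: {int(zero_sd.sum())} timepoint(s) with zero "
            "wild-type SD masked",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (resid - wt_stats.mean) / np.where(zero_sd, np.nan, sd)
    lo, hi = window
    sel = (times >= lo) & (times <= hi)
    z_win = z[sel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = float(np.nanmean(z_win)) if len(z_win) else float("nan")
    return DivergenceProfile(
        strain_id=strain_id, times=times[sel], z_t=z_win, mean_z=mean_z,
    )


@dataclass(frozen=True)
class CategoryCall:
    """Category assignment of one strain relative to the growth law."""

    strain_id: str
    category: str
    p_raw: float
    p_corrected: float
    mean_z: float


def _finite(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return z[np.isfinite(z)]


def _pooled_wt_z(wt_profiles) -> np.ndarray:
    return np.concatenate([_finite(p.z_t) for p in wt_profiles])


def wildtype_correction_factor(wt_profiles, alpha: float = 0.01) -> float:
    """Smallest multiplier that makes every wild-type profile non-significant.

    Each wild-type profile is tested against the pool of the remaining
    wild-type Z-values (leave-one-out); the factor is
    ``max(1, alpha / min p)``.  Multiplying mutant P-values by it removes
    false positives at the rate set by the wild-type cohort itself, which
    also absorbs the anticonservatism of treating (autocorrelated)
    timepoints as independent observations.
    """
    wt_profiles = list(wt_profiles)
    if len(wt_profiles) < 2:
        raise ValidationError("need >=2 wild-type profiles for the correction factor")
    zs = [_finite(p.z_t) for p in wt_profiles]
    p_min = 1.0
    for i in range(len(zs)):
        pool = np.concatenate([zs[j] for j in range(len(zs)) if j != i])
        _, p = two_sample_t(zs[i], pool)
        p_min = min(p_min, max(p, 1e-300))
    return max(1.0, alpha / p_min)


def classify_mutant(
    profile: DivergenceProfile,
    wt_profiles,
    alpha: float = 0.01,
    correction_factor: float | None = None,
) -> CategoryCall:
    """Assign one strain to category I, II or III.

    The strain's windowed Z-values are compared to the pooled wild-type
    Z-values by a two-tailed equal-variance t-test; the P-value is multiplied
    by the wild-type-derived correction factor.  Corrected P < alpha with a
    positive mean Z gives category III (faster than the law allows), with a
    negative mean Z category II; anything else is category I.
    """
    wt_profiles = list(wt_profiles)
    if len(wt_profiles) < 10:
        raise ValidationError(
            "classification refused: need >=10 wild-type profiles for a "
            f"stable variance estimate, have {len(wt_profiles)}"
        )
    if correction_factor is None:
        correction_factor = wildtype_correction_factor(wt_profiles, alpha)
    pooled = _pooled_wt_z(wt_profiles)
    z = _finite(profile.z_t)
    _, p = two_sample_t(z, pooled)
    p_corr = min(1.0, p * correction_factor)
    if p_corr < alpha and profile.mean_z > 0:
        category = CATEGORY_DECOUPLED
    elif p_corr < alpha and profile.mean_z < 0:
        category = CATEGORY_SLOW
    else:
        category = CATEGORY_WT
    return CategoryCall(
        strain_id=profile.strain_id, category=category,
        p_raw=p, p_corrected=p_corr, mean_z=profile.mean_z,
    )


def classify_cohort(
    profiles,
    wt_profiles,
    alpha: float = 0.01,
    correction: str = "wildtype_floor",
) -> list[CategoryCall]:
    """Classify a cohort of strains with a single shared correction factor.

    ``correction`` is ``"wildtype_floor"`` (default; see
    :func:`wildtype_correction_factor`) or ``"bonferroni"`` (multiply by the
    number of tested strains).
    """
    profiles = list(profiles)
    wt_profiles = list(wt_profiles)
    if correction == "wildtype_floor":
        factor = wildtype_correction_factor(wt_profiles, alpha)
    elif correction == "bonferroni":
        factor = float(max(len(profiles), 1))
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return [
        classify_mutant(p, wt_profiles, alpha=alpha, correction_factor=factor)
        for p in profiles
    ]


@dataclass
class ClusterResult:
    """Complete-linkage clustering of divergence profiles."""

    strain_ids: list[str]
    linkage: np.ndarray | None   # scipy linkage matrix; None for a single leaf
    newick: str


def _impute(profile: DivergenceProfile) -> np.ndarray:
    z = np.asarray(profile.z_t, dtype=float)
    if np.isnan(z).any():
        fill = np.nanmean(z) if np.isfinite(z).any() else 0.0
        z = np.where(np.isnan(z), fill, z)
    return z


def _newick(node, labels, parent_dist) -> str:
    length = max(parent_dist - node.dist, 0.0)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.9g}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.9g}"


def cluster_profiles(profiles) -> ClusterResult:
    """Hierarchical clustering of profiles (Euclidean metric, complete linkage).

    Profiles are ordered lexicographically by strain id before clustering, so
    the result is deterministic for a given input set regardless of input
    order.  Masked (NaN) points are imputed with the profile mean.
    """
    profiles = sorted(profiles, key=lambda p: p.strain_id)
    if not profiles:
        raise ValidationError("no profiles to cluster")
    labels = [p.strain_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate strain ids in clustering input")
    if len(profiles) == 1:
        return ClusterResult(strain_ids=labels, linkage=None,
                             newick=f"{labels[0]}:0;")
    t0 = np.asarray(profiles[0].times, dtype=float)
    for p in profiles[1:]:
        _check_grid(t0, np.asarray(p.times, float), "clustered profiles")
    X = np.vstack([_impute(p) for p in profiles])
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    tree = hierarchy.to_tree(Z)
    newick = f"({_newick(tree.left, labels, tree.dist)}," \
             f"{_newick(tree.right, labels, tree.dist)});"
    return ClusterResult(strain_ids=labels, linkage=Z, newick=newick)


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat labels from cutting the dendrogram into ``k`` clusters."""
    if result.linkage is None:
        return {result.strain_ids[0]: 1}
    flat = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.strain_ids, (int(v) for v in flat)))
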