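"""Statistics pipeline for per-cell two-channel fluorescence data.

Implements the analysis chain applied to flow-cytometry event tables:

* absolute quantitation against MESF calibration beads (log–log line fit),
* inter-day comparability by aligning the first percentile of each channel,
* one/two-component Gaussian mixture fits on log fluorescence with BIC model
  selection and a conservative bimodality filter (minimum component weight
  and mutual peak dominance),
* mutual information between channels via a James–Stein-type shrinkage
  estimator over an adaptive Bayesian-blocks discretization.

All fits and estimates operate on aligned, rescaled, log-transformed values;
mutual information is reported in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from ._errors import CalibrationError, DegenerateDataError, DomainError, SchemaError

__all__ = [
    "ExpressionSample",
    "BeadSet",
    "MesfCalibration",
    "GmmFit",
    "MiEstimate",
    "mesf_calibrate",
    "align_first_percentile",
    "fit_gmm",
    "select_model_bic",
    "bimodality_filter",
    "bayesian_blocks",
    "mi_shrinkage",
]

EVENT_COLUMNS = ("cell_id", "nanog", "reporter", "condition", "day", "replicate")


@dataclass
class ExpressionSample:
    """Per-cell two-channel fluorescence records.

    ``data`` holds one row per cell with columns
    ``cell_id, nanog, reporter, condition, day, replicate``; intensities are
    in ``units`` ("arbitrary" or "MESF").  Nonpositive intensities are
    permitted on input but are flagged (they are excluded before any
    log-transform downstream).  ``ground_truth`` carries generator metadata
    for synthetic samples and is never consulted by the pipeline itself.
    """

    data: pd.DataFrame
    units: str = "arbitrary"
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"event table is missing column(s): {', '.join(missing)}")
        for ch in ("nanog", "reporter"):
            vals = self.data[ch].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise SchemaError(f"channel {ch!r} contains non-finite values")

    def nonpositive_fraction(self, channel: str) -> float:
        v = self.data[channel].to_numpy(dtype=float)
        return float(np.mean(v <= 0))

    def positive_log(self, channel: str) -> np.ndarray:
        """Natural-log intensities of the strictly positive events."""
        v = self.data[channel].to_numpy(dtype=float)
        frac = np.mean(v <= 0)
        if frac > 0:
            warnings.warn(
                f"excluding {frac:.2%} nonpositive {channel} events before log-transform",
                stacklevel=2,
            )
        return np.log(v[v > 0])


@dataclass(frozen=True)
class BeadSet:
    """MESF calibration-bead populations: measured intensity per certified level."""

    intensity: np.ndarray
    mesf: np.ndarray

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        mesf = np.asarray(self.mesf, dtype=float)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "mesf", mesf)
        if intensity.size != mesf.size or intensity.size < 2:
            raise CalibrationError("need >= 2 paired bead levels")
        order = np.argsort(mesf)
        if not (np.all(np.diff(mesf[order]) > 0) and np.all(np.diff(intensity[order]) > 0)):
            raise CalibrationError("bead intensities must increase strictly with MESF")
        if np.any(intensity <= 0) or np.any(mesf <= 0):
            raise CalibrationError("bead intensities and MESF values must be > 0")


@dataclass(frozen=True)
class MesfCalibration:
    """Fitted log10(MESF) = intercept + slope·log10(intensity) line."""

    slope: float
    intercept: float

    def apply(self, intensity: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.intercept + self.slope * np.log10(intensity))

    def invert(self, mesf: np.ndarray) -> np.ndarray:
        return 10.0 ** ((np.log10(mesf) - self.intercept) / self.slope)


def mesf_calibrate(
    beads: BeadSet, sample: ExpressionSample, channel: str
) -> tuple[ExpressionSample, MesfCalibration]:
    """Map a channel to absolute MESF units via a least-squares log–log line.

    Returns the calibrated sample (channel replaced, units set to "MESF")
    together with the calibration coefficients.  Nonpositive events cannot be
    mapped through the log–log fit and are dropped, with the fraction
    reported as a warning.
    """
    if channel not in ("nanog", "reporter"):
        raise DomainError(f"unknown channel {channel!r}")
    slope, intercept = np.polyfit(np.log10(beads.intensity), np.log10(beads.mesf), 1)
    cal = MesfCalibration(slope=float(slope), intercept=float(intercept))
    df = sample.data.copy()
    v = df[channel].to_numpy(dtype=float)
    bad = v <= 0
    if bad.any():
        warnings.warn(
            f"dropping {bad.mean():.2%} nonpositive {channel} events during calibration",
            stacklevel=2,
        )
        df = df.loc[~bad].reset_index(drop=True)
        v = v[~bad]
    df[channel] = cal.apply(v)
    return ExpressionSample(data=df, units="MESF", ground_truth=sample.ground_truth), cal


def align_first_percentile(
    sample: ExpressionSample,
    channels: Sequence[str] = ("nanog", "reporter"),
    reference_day: Optional[int] = None,
) -> tuple[ExpressionSample, dict]:
    """Align per-day distributions at their first percentile, per channel.

    Log-scale values of each day are shifted additively (a multiplicative
    rescaling in linear units) so that the 1st percentile matches that of the
    reference day (default: the earliest day).  The shift preserves the shape
    of each day's distribution; applying the operation twice is the identity.
    Returns the aligned sample and the applied shifts in natural-log units,
    keyed by (channel, day).
    """
    df = sample.data.copy()
    days = sorted(df["day"].unique())
    if not days:
        raise DomainError("sample contains no days")
    ref = days[0] if reference_day is None else reference_day
    if ref not in days:
        raise DomainError(f"reference day {ref} not present")
    shifts: dict = {}
    for ch in channels:
        ref_vals = df.loc[df["day"] == ref, ch].to_numpy(dtype=float)
        ref_vals = ref_vals[ref_vals > 0]
        if ref_vals.size < 10:
            raise DomainError(f"reference day has <10 positive {ch} events")
        ref_q = np.percentile(np.log(ref_vals), 1)
        for day in days:
            mask = df["day"] == day
            vals = df.loc[mask, ch].to_numpy(dtype=float)
            pos = vals > 0
            if pos.sum() < 10:
                raise DomainError(f"day {day} has <10 positive {ch} events")
            shift = ref_q - np.percentile(np.log(vals[pos]), 1)
            df.loc[mask, ch] = vals * np.exp(shift)
            shifts[(ch, int(day))] = float(shift)
    return ExpressionSample(df, units=sample.units, ground_truth=sample.ground_truth), shifts


@dataclass(frozen=True)
class GmmFit:
    """A fitted 1- or 2-component Gaussian mixture on log fluorescence."""

    n_components: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    log_likelihood: float
    bic: float
    n_obs: int

    @property
    def n_params(self) -> int:
        return 3 * self.n_components - 1


def fit_gmm(values: np.ndarray, k: int, seed: int = 0) -> GmmFit:
    """EM fit of a k-component (k ∈ {1,2}) Gaussian mixture.

    Ten random restarts plus one quantile-initialized start; convergence when
    the per-step log-likelihood gain falls below 1e−9; component variances
    floored at 1e−6 times the data variance.  Components are reported in
    order of increasing mean.  BIC = −2·loglik + p·ln(n) with p = 3k−1.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if k not in (1, 2):
        raise DomainError("k must be 1 or 2")
    if values.size < 20:
        raise DegenerateDataError("need >= 20 finite values")
    var = float(np.var(values))
    if var == 0:
        raise DegenerateDataError("all values identical")
    X = values.reshape(-1, 1)
    reg = 1e-6 * var

    # stage 1: ten random restarts plus a quantile-based start, screened at a
    # loose tolerance; stage 2: polish the best candidate to full convergence
    # (per-sample tolerance 1e-12·n ~ total log-likelihood gain below 1e-8)
    screen = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=1e-4,
        reg_covar=reg,
        max_iter=200,
        n_init=10,
        init_params="random_from_data",
        random_state=seed,
    ).fit(X)
    qmeans = np.quantile(values, [(2 * i + 1) / (2 * k) for i in range(k)]).reshape(-1, 1)
    screen_q = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=1e-4,
        reg_covar=reg,
        max_iter=200,
        n_init=1,
        means_init=qmeans,
        random_state=seed,
    ).fit(X)
    cand = screen_q if screen_q.score(X) > screen.score(X) else screen
    best = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=max(1e-8 / values.size, 1e-12),
        reg_covar=reg,
        max_iter=5000,
        n_init=1,
        weights_init=cand.weights_,
        means_init=cand.means_,
        precisions_init=cand.precisions_,
        random_state=seed,
    ).fit(X)

    order = np.argsort(best.means_.ravel())
    weights = tuple(float(w) for w in best.weights_.ravel()[order])
    means = tuple(float(m) for m in best.means_.ravel()[order])
    sds = tuple(float(np.sqrt(c)) for c in best.covariances_.ravel()[order])
    loglik = float(best.score(X) * values.size)
    p = 3 * k - 1
    bic = -2.0 * loglik + p * np.log(values.size)
    return GmmFit(
        n_components=k,
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=loglik,
        bic=float(bic),
        n_obs=int(values.size),
    )


def select_model_bic(fit1: GmmFit, fit2: GmmFit) -> GmmFit:
    """Choose between the 1- and 2-component fits by BIC (ties → 1 component)."""
    if fit1.n_obs != fit2.n_obs:
        raise DomainError("fits compare different sample sizes")
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise DomainError("expected a k=1 fit and a k=2 fit")
    return fit2 if fit2.bic < fit1.bic else fit1


def bimodality_filter(fit2: GmmFit) -> tuple[bool, list[str]]:
    """Robust-bimodality criteria for a 2-component fit.

    Accept iff (a) both component weights exceed 0.1 and (b) each component's
    weighted peak density exceeds the other component's weighted density at
    that same point (the component mean), so neither mode is buried under the
    other's flank.  Returns the verdict with machine-readable reason codes
    for any failures.
    """
    if fit2.n_components != 2:
        raise DomainError("bimodality filter requires a 2-component fit")
    reasons: list[str] = []
    if min(fit2.weights) <= 0.1:
        reasons.append("weight")
    (w1, w2), (m1, m2), (s1, s2) = fit2.weights, fit2.means, fit2.sds
    peak1_own = w1 * norm.pdf(m1, m1, s1)
    peak1_other = w2 * norm.pdf(m1, m2, s2)
    peak2_own = w2 * norm.pdf(m2, m2, s2)
    peak2_other = w1 * norm.pdf(m2, m1, s1)
    if not (peak1_own > peak1_other and peak2_own > peak2_other):
        reasons.append("peak-dominance")
    return (len(reasons) == 0), reasons


def bayesian_blocks(values: np.ndarray, p0: float = 0.05) -> np.ndarray:
    """Adaptive histogram edges by optimal piecewise-constant segmentation.

    Dynamic-programming change-point search with the standard event fitness
    ``N·ln(N/T)`` per block and a prior penalty calibrated to a false-alarm
    rate ``p0`` (``ncp_prior = 4 − ln(73.53·p0·N^−0.478)``).  Tied values are
    aggregated as weighted events, so the result depends only on the set of
    distinct values and their multiplicities.  Returns strictly increasing
    edges spanning the data; fewer than 4 distinct values fall back to a
    single bin with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateDataError("no finite values to segment")
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size < 4:
        warnings.warn("fewer than 4 distinct values; returning a single bin", stacklevel=2)
        lo, hi = float(uniq[0]), float(uniq[-1])
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return np.array([lo, hi])

    N = uniq.size
    # cell boundaries: Voronoi midpoints, outer edges at the extreme values
    edges = np.concatenate([[uniq[0]], 0.5 * (uniq[1:] + uniq[:-1]), [uniq[-1]]])
    block_length = edges[-1] - edges  # length from each boundary to the end
    cum_counts = np.concatenate([[0], np.cumsum(counts)])
    ncp_prior = 4.0 - np.log(73.53 * p0 * N ** (-0.478))

    best = np.zeros(N)
    last = np.zeros(N, dtype=int)
    for r in range(N):
        widths = block_length[: r + 1] - block_length[r + 1]
        widths = np.maximum(widths, 1e-300)
        nk = cum_counts[r + 1] - cum_counts[: r + 1]
        fitness = nk * (np.log(nk) - np.log(widths))
        total = fitness - ncp_prior
        total[1:] += best[:r]
        imax = int(np.argmax(total))
        last[r] = imax
        best[r] = total[imax]

    change_points = []
    i = N
    while i > 0:
        change_points.append(last[i - 1])
        i = last[i - 1]
    change_points = np.array(sorted(set(change_points + [N])))
    return edges[change_points]


@dataclass(frozen=True)
class MiEstimate:
    """Shrinkage mutual-information estimate over a blockwise discretization."""

    value: float  # nats
    x_edges: np.ndarray
    y_edges: np.ndarray
    joint_counts: np.ndarray
    shrinkage: float  # James–Stein intensity λ* in [0, 1]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mi_shrinkage(x: np.ndarray, y: np.ndarray, p0: float = 0.05) -> MiEstimate:
    """Mutual information (nats) between paired observations.

    Each variable is discretized separately by :func:`bayesian_blocks`; the
    joint contingency table is shrunk toward the uniform distribution over
    its occupied cells with the closed-form optimal James–Stein intensity
    λ* (clipped to [0, 1]), and MI is computed from the shrunken joint and
    its margins.  Symmetric in its arguments; nonnegative by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 20:
        raise DegenerateDataError("need >= 20 paired observations")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xe = bayesian_blocks(x, p0=p0)
        ye = bayesian_blocks(y, p0=p0)
    if xe.size < 3 or ye.size < 3:
        if xe.size == 2 and ye.size == 2:
            warnings.warn("degenerate single-bin margins; MI = 0", stacklevel=2)
            return MiEstimate(0.0, xe, ye, np.array([[float(n)]]), 0.0)
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])

    theta = counts.ravel() / n
    occupied = theta > 0
    target = np.where(occupied, 1.0 / occupied.sum(), 0.0)
    denom = (n - 1) * np.sum((target - theta) ** 2)
    lam = 0.0 if denom <= 0 else float(np.clip((1.0 - np.sum(theta**2)) / denom, 0.0, 1.0))
    p = lam * target + (1.0 - lam) * theta
    p = p.reshape(counts.shape)

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    mi = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz]))))
    return MiEstimate(
        value=max(mi, 0.0),
        x_edges=xe,
        y_edges=ye,
        joint_counts=counts,
        shrinkage=lam,
    )
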