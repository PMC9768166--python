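"""Film spring constants from AFM approach curves.

Pipeline: calibrate the optical lever sensitivity on a glass curve,
convert photodiode volts to deflection, find the contact point, split
the post-contact travel into cantilever deflection and film deformation
(springs in series), and fit force versus film deformation with total
least squares (orthogonal regression).  The TLS slope, computed in
(nm, nN) units, is the film spring constant in N/m.

Conventions chosen where the procedure leaves freedom: the baseline is
the leading 15% of the record; contact is the first point exceeding
baseline mean + 3 sd for 5 consecutive samples; fits shorter than
20 post-contact samples are rejected; only approach segments are
analyzed (loading each square once avoids hysteresis, so there is no
retract analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .types import ForceCurve

__all__ = [
    "SpringFit",
    "FilmStiffnessSummary",
    "NoiseSpectrum",
    "calibrate_sensitivity",
    "to_deflection",
    "detect_contact",
    "decompose",
    "fit_tls",
    "estimate_film_stiffness",
    "summarize",
    "noise_spectrum",
]

logger = logging.getLogger(__name__)

#: defaults of the contact detector (baseline fraction, sd multiplier, run length)
BASELINE_FRACTION = 0.15
CONTACT_SD_MULTIPLIER = 3.0
CONTACT_RUN_LENGTH = 5
MIN_FIT_POINTS = 20


@dataclass
class SpringFit:
    """Per-curve film spring constant with fit diagnostics."""

    k_f: float  # N/m
    slope_ci: float  # half-width of ~95% CI, N/m
    contact_index: int
    n_points: int
    residual_rms: float  # RMS orthogonal residual in the (nm, nN) plane
    loading_rate: float | None = None
    square_id: str | None = None
    valid: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class FilmStiffnessSummary:
    """Mean/sd of film spring constants, pooled and per loading rate.

    ``t_statistic``/``p_value`` come from a two-tailed Student's t test
    assuming equal variance between exactly two rate groups, and are
    ``None`` otherwise.
    """

    k_values: list[float]
    mean: float
    sd: float
    groups: dict[float, list[float]]
    group_mean: dict[float, float]
    group_sd: dict[float, float]
    t_statistic: float | None = None
    p_value: float | None = None
    n_rejected: int = 0


def detect_contact(
    curve: ForceCurve,
    baseline_fraction: float = BASELINE_FRACTION,
    sd_multiplier: float = CONTACT_SD_MULTIPLIER,
    run_length: int = CONTACT_RUN_LENGTH,
) -> int:
    """Index of the first sustained departure from the baseline.

    Baseline mean and sd are estimated on the leading
    ``baseline_fraction`` of the record; contact is the first sample
    whose channel exceeds mean + ``sd_multiplier``*sd for ``run_length``
    consecutive samples.

    Raises
    ------
    ValueError
        If no sustained crossing exists ("no contact found").
    """
    y = curve.channel
    n = len(y)
    n_base = max(int(baseline_fraction * n), 2)
    base = y[:n_base]
    threshold = base.mean() + sd_multiplier * base.std(ddof=1)
    above = y > threshold
    # first index opening a run of `run_length` consecutive True
    run = np.convolve(above.astype(int), np.ones(run_length, dtype=int), mode="valid")
    hits = np.flatnonzero(run == run_length)
    if len(hits) == 0:
        raise ValueError("no contact found: channel never leaves the baseline")
    return int(hits[0])


def calibrate_sensitivity(
    glass_curve: ForceCurve,
    nominal_sensitivity: float | None = None,
) -> float:
    """Optical lever sensitivity S (nm/V) from a rigid-substrate scan.

    On glass the cantilever deflects one-for-one with the piezo, so the
    inverse slope of signal versus piezo in the contact region is S.
    Computed as the ordinary least-squares slope of piezo (nm) against
    signal (V) past the detected contact.

    If ``nominal_sensitivity`` is given and the fitted S exceeds it by
    more than 10%, a warning flags visible film compliance (a compliant
    surface inflates nm per volt).
    """
    if not glass_curve.in_volts:
        raise ValueError("calibration curve must be in photodiode volts")
    contact = detect_contact(glass_curve)
    z = glass_curve.piezo[contact:]
    v = glass_curve.signal[contact:]
    if len(z) < MIN_FIT_POINTS:
        raise ValueError("contact region too short for sensitivity calibration")
    if np.ptp(v) == 0:
        raise ValueError("degenerate signal in contact region")
    slope = np.polyfit(v, z, 1)[0]
    if slope <= 0:
        raise ValueError("non-physical (non-positive) sensitivity slope")
    if nominal_sensitivity is not None and slope > 1.1 * nominal_sensitivity:
        warnings.warn(
            f"fitted sensitivity {slope:.2f} nm/V exceeds nominal "
            f"{nominal_sensitivity:.2f} nm/V by >10%: film compliance may be "
            "visible; calibrate on a rigid substrate",
            stacklevel=2,
        )
    return float(slope)


def to_deflection(curve: ForceCurve, sensitivity: float) -> ForceCurve:
    """Convert a photodiode-volt curve to deflection in nm."""
    if not curve.in_volts:
        raise ValueError("curve is already in deflection units")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    meta = dict(curve.meta)
    meta["sensitivity"] = sensitivity
    return ForceCurve(
        time=curve.time,
        piezo=curve.piezo,
        deflection=sensitivity * curve.signal,
        loading_rate=curve.loading_rate,
        square_id=curve.square_id,
        meta=meta,
    )


def decompose(
    curve: ForceCurve, cantilever_k: float, contact: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split post-contact travel into film deformation and applied force.

    For samples past the contact index, the film deformation is the
    piezo travel minus the baseline-corrected cantilever deflection,
    and the force is cantilever stiffness times deflection:

        δ_f = (z − z_contact) − (d − d_baseline)      [nm]
        F   = k_c (d − d_baseline)                     [nN]
    """
    if cantilever_k <= 0:
        raise ValueError("cantilever_k must be positive")
    if curve.in_volts:
        raise ValueError("decompose requires a deflection (nm) channel")
    if not 0 <= contact < len(curve):
        raise ValueError("contact index out of range")
    d = curve.deflection
    z = curve.piezo
    d_base = float(d[:contact].mean()) if contact > 0 else 0.0
    dc = d[contact:] - d_base
    delta_f = (z[contact:] - z[contact]) - dc
    force = cantilever_k * dc
    return delta_f, force


def _tls_bootstrap_ci(x: np.ndarray, y: np.ndarray, n_boot: int = 200) -> float:
    """~95% half-width CI of the TLS slope by pair bootstrap (seeded)."""
    n = len(x)
    rng = np.random.default_rng(12345)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        xc, yc = xb - xb.mean(), yb - yb.mean()
        sxx, syy, sxy = xc @ xc, yc @ yc, xc @ yc
        if sxy == 0:
            slopes[b] = 0.0
            continue
        slopes[b] = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def fit_tls(
    delta_f: np.ndarray,
    force: np.ndarray,
    min_points: int = MIN_FIT_POINTS,
    loading_rate: float | None = None,
    square_id: str | None = None,
    contact_index: int = 0,
) -> SpringFit:
    """Total least squares (orthogonal regression) slope in N/m.

    The slope is the orientation of the first principal axis of the
    centered (δ_f [nm], F [nN]) scatter, obtained from the SVD of the
    centered data matrix; the intercept passes through the centroid.
    TLS is scale dependent, so the fit is always carried out in
    (nm, nN), making the slope a stiffness in N/m directly.

    Negative slopes are flagged (``valid=False``) rather than silently
    returned; zero-variance scatter raises.
    """
    x = np.asarray(delta_f, dtype=float)
    y = np.asarray(force, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("delta_f and force must be equal-length 1D arrays")
    if len(x) < min_points:
        raise ValueError(f"need at least {min_points} points for a fit, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in fit input")
    xc = x - x.mean()
    yc = y - y.mean()
    if np.all(xc == 0) and np.all(yc == 0):
        raise ValueError("degenerate scatter: zero variance in both coordinates")
    data = np.column_stack([xc, yc])
    _, s, vt = np.linalg.svd(data, full_matrices=False)
    direction = vt[0]
    if direction[0] == 0:
        raise ValueError("degenerate scatter: vertical principal axis (infinite slope)")
    slope = float(direction[1] / direction[0])
    residual_rms = float(s[1] / np.sqrt(len(x)))  # orthogonal residual RMS

    fit = SpringFit(
        k_f=slope,
        slope_ci=_tls_bootstrap_ci(x, y),
        contact_index=contact_index,
        n_points=len(x),
        residual_rms=residual_rms,
        loading_rate=loading_rate,
        square_id=square_id,
    )
    if slope <= 0:
        fit.valid = False
        fit.flags.append("non-positive slope")
        logger.info("TLS fit rejected (slope %.4g N/m <= 0) for %s", slope, square_id)
    return fit


def estimate_film_stiffness(
    curve: ForceCurve,
    cantilever_k: float,
    sensitivity: float | None = None,
    **contact_kwargs,
) -> SpringFit:
    """End-to-end per-curve estimate: convert, find contact, decompose, fit."""
    if curve.in_volts:
        if sensitivity is None:
            raise ValueError("a volt-channel curve needs a sensitivity (nm/V)")
        curve = to_deflection(curve, sensitivity)
    contact = detect_contact(curve, **contact_kwargs)
    delta_f, force = decompose(curve, cantilever_k, contact)
    return fit_tls(
        delta_f,
        force,
        loading_rate=curve.loading_rate,
        square_id=curve.square_id,
        contact_index=contact,
    )


def summarize(fits: list[SpringFit]) -> FilmStiffnessSummary:
    """Aggregate per-square spring constants, grouped by loading rate.

    Invalid (flagged) fits are excluded with a logged reason.  With
    exactly two rate groups of >= 2 fits each, a two-tailed Student's
    t test assuming equal variance compares them; otherwise the t
    fields stay ``None``.
    """
    accepted = [f for f in fits if f.valid]
    n_rejected = len(fits) - len(accepted)
    for f in fits:
        if not f.valid:
            logger.info("excluding fit for %s: %s", f.square_id, "; ".join(f.flags))
    if not accepted:
        raise ValueError("no valid fits to summarize")

    k_values = [f.k_f for f in accepted]
    groups: dict[float, list[float]] = {}
    for f in accepted:
        groups.setdefault(f.loading_rate if f.loading_rate is not None else np.nan, []).append(f.k_f)

    group_mean = {r: float(np.mean(v)) for r, v in groups.items()}
    group_sd = {r: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for r, v in groups.items()}

    t_stat = p_val = None
    if len(groups) == 2:
        (ra, va), (rb, vb) = sorted(groups.items())
        if len(va) >= 2 and len(vb) >= 2:
            if np.var(va) == 0 and np.var(vb) == 0:
                # degenerate but well-defined: identical spread-free groups
                equal = np.mean(va) == np.mean(vb)
                t_stat = 0.0 if equal else float(np.inf) * np.sign(np.mean(va) - np.mean(vb))
                p_val = 1.0 if equal else 0.0
            else:
                res = stats.ttest_ind(va, vb, equal_var=True)
                t_stat, p_val = float(res.statistic), float(res.pvalue)

    return FilmStiffnessSummary(
        k_values=k_values,
        mean=float(np.mean(k_values)),
        sd=float(np.std(k_values, ddof=1)) if len(k_values) > 1 else 0.0,
        groups=groups,
        group_mean=group_mean,
        group_sd=group_sd,
        t_statistic=t_stat,
        p_value=p_val,
        n_rejected=n_rejected,
    )


@dataclass
class NoiseSpectrum:
    """Averaged periodogram of the deflection channel with detected peaks."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray
    peaks: np.ndarray  # Hz, subset of `frequencies`


def noise_spectrum(
    curve: ForceCurve,
    peak_factor: float = 10.0,
    nperseg: int | None = None,
    min_frequency: float = 20.0,
) -> NoiseSpectrum:
    """Welch spectrum of the (linearly detrended) measured channel.

    Peaks are local maxima exceeding ``peak_factor`` times the median
    power, at or above ``min_frequency``: the deterministic approach
    ramp has a kink at contact whose residual (after the per-segment
    linear detrend) leaks into the lowest few bins, so sub-20 Hz maxima
    reflect curve shape rather than interference.  Segment averaging
    keeps the white-noise floor tight enough that the 10x-median
    threshold rarely fires on noise alone.

    Raises on a non-uniform time base (the FFT assumes even sampling).
    """
    t = curve.time
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("non-uniform time base: spectrum requires even sampling")
    fs = 1.0 / dt[0]
    y = sps.detrend(curve.channel, type="linear")
    if nperseg is None:
        nperseg = min(len(y), max(int(round(fs / 4.0)), 32))
    freqs, power = sps.welch(y, fs=fs, nperseg=nperseg, detrend="linear")
    floor = np.median(power)
    idx, _ = sps.find_peaks(power, height=peak_factor * floor)
    idx = idx[freqs[idx] >= min_frequency]
    return NoiseSpectrum(frequencies=freqs, power=power, peaks=freqs[idx])
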