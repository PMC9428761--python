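"""Fixed-period cosinor rhythmometry.

Fits the single-component sinusoid

    X(t) = a + c * sin(2*pi*t/24 + b)

to a time series by ordinary least squares on its linearisation

    X(t) = a + [c*sin(b)] * cos(2*pi*t/24) + [c*cos(b)] * sin(2*pi*t/24),

with the period fixed at exactly 24 h. ``a`` is the mesor (rhythm-adjusted
mean), ``c >= 0`` the amplitude and ``b`` the acrophase in radians; the peak
time in hours is ``((pi/2 - b) mod 2*pi) * 24/(2*pi)``. Rhythm detection is
the joint F-test of the two trigonometric regressors against the
intercept-only model. Between-condition comparisons of amplitude and peak
time use the paired t-test across participants, with peak-time differences
wrapped to (-12, 12] hours before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PERIOD_H, HormoneSeries, wrap_hours

_OMEGA = 2 * np.pi / PERIOD_H

#: amplitudes below this (in analyte units) are treated as "no rhythm";
#: the peak time is then undefined.
AMPLITUDE_EPS = 1e-9


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosinor fit of one series."""

    mesor_a: float
    amplitude_c: float
    acrophase_b: float          # radians in [0, 2*pi)
    peak_time_h: float          # hours in [0, 24); NaN if amplitude ~ 0
    coef_cos: float             # c*sin(b)
    coef_sin: float             # c*cos(b)
    residual_sd: float
    n: int
    amplitude_se: float
    peak_time_se_h: float
    rhythm_F_p: float
    participant_id: str = ""
    condition: str = ""
    analyte: str = ""

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.mesor_a + self.amplitude_c * np.sin(_OMEGA * t + self.acrophase_b)


def fit_cosinor(series_or_times, concentrations=None, **meta) -> CosinorFit:
    """Fit the 24-h cosinor model by linearised OLS.

    Accepts either a :class:`~desyncflow.io.HormoneSeries` or explicit
    ``(times_h, values)`` arrays. Requires >= 4 points spanning >= 8 h
    (shorter spans make the trigonometric design near-singular).
    """
    if isinstance(series_or_times, HormoneSeries):
        s = series_or_times
        t, y = s.times_h, s.concentrations
        meta = {"participant_id": s.participant_id, "condition": s.condition,
                "analyte": s.analyte, **meta}
    else:
        t = np.asarray(series_or_times, dtype=float)
        y = np.asarray(concentrations, dtype=float)

    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    n = len(t)
    if n < 4:
        raise ValueError(f"cosinor fit needs >= 4 points, got {n}")
    if np.ptp(t) < 8.0:
        raise ValueError("time span < 8 h: design near-singular")

    X = np.column_stack([np.ones(n), np.cos(_OMEGA * t), np.sin(_OMEGA * t)])
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular cosinor design") from exc

    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - 3
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = np.linalg.inv(XtX) * sigma2

    a, coef_cos, coef_sin = beta
    c = math.hypot(coef_cos, coef_sin)
    b = math.atan2(coef_cos, coef_sin) % (2 * np.pi)
    peak = ((np.pi / 2 - b) % (2 * np.pi)) * PERIOD_H / (2 * np.pi)

    # joint F-test of the two trig terms vs intercept-only
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if dof > 0 and rss > 0:
        F = ((rss0 - rss) / 2) / (rss / dof)
        p_rhythm = float(stats.f.sf(F, 2, dof))
    else:
        p_rhythm = np.nan if dof <= 0 else 0.0

    # delta method on (coef_cos, coef_sin) for SEs of c and of the peak time
    if c > AMPLITUDE_EPS and np.isfinite(sigma2):
        g_amp = np.array([coef_cos / c, coef_sin / c])
        amp_se = float(np.sqrt(g_amp @ cov[1:, 1:] @ g_amp))
        # b = atan2(cc, cs); db/dcc = cs/c^2, db/dcs = -cc/c^2
        g_b = np.array([coef_sin / c**2, -coef_cos / c**2])
        b_se = float(np.sqrt(g_b @ cov[1:, 1:] @ g_b))
        peak_se = b_se * PERIOD_H / (2 * np.pi)
    else:
        amp_se = float(np.sqrt(np.trace(cov[1:, 1:]) / 2)) if np.isfinite(sigma2) else np.nan
        peak_se = np.nan
        peak = np.nan  # amplitude ~ 0: peak undefined

    return CosinorFit(
        mesor_a=float(a), amplitude_c=float(c), acrophase_b=float(b),
        peak_time_h=float(peak), coef_cos=float(coef_cos), coef_sin=float(coef_sin),
        residual_sd=float(np.sqrt(sigma2)) if dof > 0 else np.nan,
        n=n, amplitude_se=amp_se, peak_time_se_h=peak_se, rhythm_F_p=p_rhythm,
        **meta,
    )


def fit_cohort(series_list) -> list:
    """Fit every series in a list; returns fits in input order."""
    return [fit_cosinor(s) for s in series_list]


# ---------------------------------------------------------------------------
# Between-condition comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhythmComparison:
    """Paired comparison of cosinor parameters between sleep conditions."""

    analyte: str
    n_pairs: int
    n_dropped: int                       # participants lacking a usable pair
    pairs: pd.DataFrame                  # per-participant fits and differences
    mean_amplitude_diff: float
    se_amplitude_diff: float
    t_amplitude: float
    p_amplitude: float
    mean_peak_diff_h: float              # mean of wrapped (out - in) peak times
    se_peak_diff_h: float
    t_peak: float
    p_peak: float
    n_peak_pairs: int                    # pairs with defined peak both conditions


def _paired_t(d: np.ndarray):
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else np.nan
    se = sd / math.sqrt(n)
    if se == 0:
        t = 0.0 if mean == 0 else math.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / se
        p = 2 * stats.t.sf(abs(t), n - 1)
    return mean, se, float(t), float(p)


def compare_rhythms(fits_in, fits_out, analyte: str = "") -> RhythmComparison:
    """Paired t-tests of amplitude and (wrapped) peak-time differences.

    ``fits_in`` and ``fits_out`` are mappings participant_id -> CosinorFit
    (lists of fits are keyed by their ``participant_id``). Participants
    lacking either condition are dropped and counted; pairs with an
    undefined peak in either condition are excluded from the peak-time test
    only.
    """
    if not isinstance(fits_in, dict):
        fits_in = {f.participant_id: f for f in fits_in}
    if not isinstance(fits_out, dict):
        fits_out = {f.participant_id: f for f in fits_out}
    common = sorted(set(fits_in) & set(fits_out))
    n_dropped = len(set(fits_in) ^ set(fits_out))
    if len(common) < 2:
        raise ValueError("paired comparison needs >= 2 matched participants")

    rows = []
    for pid in common:
        fi, fo = fits_in[pid], fits_out[pid]
        peak_diff = (
            wrap_hours(fo.peak_time_h - fi.peak_time_h)
            if np.isfinite(fo.peak_time_h) and np.isfinite(fi.peak_time_h)
            else np.nan
        )
        rows.append({
            "participant_id": pid,
            "amplitude_in": fi.amplitude_c, "amplitude_out": fo.amplitude_c,
            "peak_in_h": fi.peak_time_h, "peak_out_h": fo.peak_time_h,
            "amplitude_diff": fo.amplitude_c - fi.amplitude_c,
            "peak_diff_h": peak_diff,
        })
    pairs = pd.DataFrame(rows)

    amp_mean, amp_se, amp_t, amp_p = _paired_t(pairs["amplitude_diff"].to_numpy())
    peak_d = pairs["peak_diff_h"].dropna().to_numpy()
    if len(peak_d) >= 2:
        pk_mean, pk_se, pk_t, pk_p = _paired_t(peak_d)
    else:
        pk_mean = pk_se = pk_t = pk_p = np.nan

    return RhythmComparison(
        analyte=analyte, n_pairs=len(common), n_dropped=n_dropped, pairs=pairs,
        mean_amplitude_diff=amp_mean, se_amplitude_diff=amp_se,
        t_amplitude=amp_t, p_amplitude=amp_p,
        mean_peak_diff_h=pk_mean, se_peak_diff_h=pk_se,
        t_peak=pk_t, p_peak=pk_p, n_peak_pairs=len(peak_d),
    )


# ---------------------------------------------------------------------------
# Tabular round-trip
# ---------------------------------------------------------------------------

_FIT_COLUMNS = [
    "participant_id", "condition", "analyte", "mesor_a", "amplitude_c",
    "acrophase_b", "peak_time_h", "coef_cos", "coef_sin", "residual_sd",
    "n", "amplitude_se", "peak_time_se_h", "rhythm_F_p",
]


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(f, c) for c in _FIT_COLUMNS} for f in fits])


def write_fits(fits, path) -> None:
    fits_to_frame(fits).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fits(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    return [
        CosinorFit(**{c: row[c] for c in _FIT_COLUMNS if c not in ("n",)},
                   n=int(row["n"]))
        for _, row in df.iterrows()
    ]


def comparison_to_frame(cmp: RhythmComparison) -> pd.DataFrame:
    """One-row summary table of a rhythm comparison."""
    return pd.DataFrame([{
        "analyte": cmp.analyte, "n_pairs": cmp.n_pairs, "n_dropped": cmp.n_dropped,
        "mean_amplitude_diff": cmp.mean_amplitude_diff,
        "se_amplitude_diff": cmp.se_amplitude_diff,
        "t_amplitude": cmp.t_amplitude, "p_amplitude": cmp.p_amplitude,
        "mean_peak_diff_h": cmp.mean_peak_diff_h,
        "se_peak_diff_h": cmp.se_peak_diff_h,
        "t_peak": cmp.t_peak, "p_peak": cmp.p_peak,
        "n_peak_pairs": cmp.n_peak_pairs,
    }])
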