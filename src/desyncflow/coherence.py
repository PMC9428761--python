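"""Temporal coherence of transcripts with a designated regulator.

For each probe and sleep condition, expression is averaged across
participants at each sampling time point to give a mean temporal profile.
Two statistics relate every probe to a designated regulator transcript
(SP1-like hub):

* the Pearson correlation (and two-sided p) between the probe's and the
  regulator's mean profiles, computed over all 7 time points;
* the circular cross-correlation phase lag: both profiles restricted to
  time points 1-6 (point 7 is the same clock time as point 1, 24 h later,
  so it cannot participate in cyclic shifting), z-scored, and correlated
  under all cyclic shifts of the 4-h grid; the lag is the shift with
  maximum correlation, reported in hours wrapped to (-12, 12].

Sign convention: a positive lag means the probe's profile peaks *later*
than the regulator's. Ties in the maximum correlation are broken toward
the smallest absolute lag, then toward the negative lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, IN_PHASE, OUT_OF_PHASE, PERIOD_H, ExpressionDataset, wrap_hours


@dataclass(frozen=True)
class MeanProfile:
    """Across-participant mean expression at each sampling time point."""

    probe_id: str
    condition: str
    times_h: np.ndarray
    means: np.ndarray
    n_participants: np.ndarray

    def __len__(self) -> int:
        return len(self.times_h)


def mean_profile(data: ExpressionDataset, probe: str, condition: str) -> MeanProfile:
    """Average a probe's expression across participants per time point.

    Missing values are dropped per point, with the per-point n recorded;
    a time point with no observation at all is an error.
    """
    if probe not in data.values.index:
        raise KeyError(f"probe {probe!r} not in dataset")
    mask = data.samples["condition"] == condition
    sub = data.samples.loc[mask]
    y = data.values.loc[probe, sub["sample_id"]].to_numpy()
    times = np.sort(sub["clock_time_h"].unique())
    means = np.empty(len(times))
    counts = np.empty(len(times), dtype=int)
    tcol = sub["clock_time_h"].to_numpy()
    for i, t in enumerate(times):
        vals = y[tcol == t]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"probe {probe!r}: no observations at t={t} h "
                             f"({condition})")
        means[i] = vals.mean()
        counts[i] = len(vals)
    return MeanProfile(probe_id=probe, condition=condition,
                       times_h=times, means=means, n_participants=counts)


def profile_correlation(p1: MeanProfile, p2: MeanProfile):
    """Pearson r and two-sided p between two mean profiles (all points)."""
    if p1.condition != p2.condition:
        raise ValueError("profiles from different conditions")
    if not np.array_equal(p1.times_h, p2.times_h):
        raise ValueError("profiles on different time grids")
    a, b = p1.means, p2.means
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete points for correlation")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a profile")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score profile")
    return (x - np.mean(x)) / sd


def circular_xcorr(p1, p2, interval_h: float = None):
    """Circular cross-correlation lag between two profiles.

    ``p1`` is the reference (regulator) and ``p2`` the probe; the returned
    ``(lag_h, max_corr)`` has positive lag when ``p2`` lags behind (peaks
    after) ``p1``. Profiles may be :class:`MeanProfile` (the closing point
    that duplicates the first clock time is dropped) or plain vectors
    already restricted to one cycle.
    """
    if isinstance(p1, MeanProfile):
        if interval_h is None:
            interval_h = float(np.diff(p1.times_h).min())
        a = p1.means[:-1]       # drop closing point (t1 + 24 h)
        b = p2.means[:-1]
    else:
        a = np.asarray(p1, dtype=float)
        b = np.asarray(p2, dtype=float)
        if interval_h is None:
            interval_h = 4.0
    if a.shape != b.shape:
        raise ValueError("profiles of different lengths")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("circular cross-correlation needs complete profiles")
    a = _zscore(a)
    b = _zscore(b)
    m = len(a)

    best = None
    for s in range(m):
        # rolling the reference forward by s matches a probe delayed by s steps
        c = float(np.dot(np.roll(a, s), b)) / ((m - 1))
        lag = wrap_hours(s * interval_h)
        key = (-round(c, 12), abs(lag), lag)   # tie-break: |lag| then negative
        if best is None or key < best[0]:
            best = (key, lag, c)
    _, lag_h, max_corr = best
    return float(lag_h), float(max_corr)


# ---------------------------------------------------------------------------
# Whole-table analysis
# ---------------------------------------------------------------------------

def resolve_regulator(data: ExpressionDataset, identifier: str) -> str:
    """Map a regulator probe id or gene symbol to a unique probe id."""
    if identifier in data.values.index:
        return identifier
    probes = data.probes_for_gene(identifier)
    if not probes:
        raise KeyError(f"regulator {identifier!r} not found in dataset")
    if len(probes) > 1:
        raise ValueError(f"gene {identifier!r} has multiple probes {probes}; "
                         "pass a probe id")
    return probes[0]


def coherence_table(data: ExpressionDataset, regulator: str,
                    probes=None, screen_results: pd.DataFrame = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe coherence statistics versus the regulator, both conditions.

    Returns one row per probe: Pearson r/p per condition, circular lag per
    condition, the wrapped lag difference (out - in), the maximum circular
    correlations, and (if screen results are given) the affected flag so
    affected and unaffected transcripts can be contrasted.
    """
    reg_probe = resolve_regulator(data, regulator)
    if probes is None:
        probes = [p for p in data.values.index if p != reg_probe]
    reg_profiles = {c: mean_profile(data, reg_probe, c) for c in CONDITIONS}

    affected_map = {}
    if screen_results is not None:
        affected_map = dict(zip(screen_results["probe_id"],
                                screen_results["affected"]))
    rows = []
    for probe in probes:
        row = {"probe_id": probe,
               "gene_symbol": data.gene_symbols.get(probe, ""),
               "regulator_probe": reg_probe}
        for cond, tag in ((IN_PHASE, "in"), (OUT_OF_PHASE, "out")):
            prof = mean_profile(data, probe, cond)
            r, p = profile_correlation(reg_profiles[cond], prof)
            lag, mc = circular_xcorr(reg_profiles[cond], prof)
            row[f"r_{tag}"] = r
            row[f"p_{tag}"] = p
            row[f"lag_{tag}_h"] = lag
            row[f"max_xcorr_{tag}"] = mc
        row["lag_diff_h"] = wrap_hours(row["lag_out_h"] - row["lag_in_h"])
        row["sig_corr_in"] = row["p_in"] < alpha
        row["sig_corr_out"] = row["p_out"] < alpha
        if affected_map:
            row["affected"] = bool(affected_map.get(probe, False))
        rows.append(row)
    return pd.DataFrame(rows)


def _circular_stats(lags_h: np.ndarray):
    """Circular mean (hours) and resultant length of a set of lags."""
    ang = np.asarray(lags_h, dtype=float) * 2 * np.pi / PERIOD_H
    z = np.mean(np.exp(1j * ang))
    mean_h = wrap_hours(np.angle(z) * PERIOD_H / (2 * np.pi))
    return float(mean_h), float(np.abs(z))


def lag_summary(coherence: pd.DataFrame) -> pd.DataFrame:
    """Polar-style summary of lags and lag differences by affected status.

    The resultant length R in [0, 1] measures lag concentration (1 = all
    probes share one lag); a tight cluster of unchanged lags in the
    affected group mirrors regulator-locked timing.
    """
    if "affected" in coherence.columns:
        groups = coherence.groupby("affected")
    else:
        groups = [(None, coherence)]
    rows = []
    for label, grp in groups:
        for col, name in (("lag_in_h", "lag_in"), ("lag_out_h", "lag_out"),
                          ("lag_diff_h", "lag_diff")):
            mean_h, R = _circular_stats(grp[col].to_numpy())
            rows.append({"affected": label, "quantity": name, "n": len(grp),
                         "circular_mean_h": mean_h, "resultant_length": R,
                         "n_sig_corr_in": int(grp["sig_corr_in"].sum()),
                         "n_sig_corr_out": int(grp["sig_corr_out"].sum())})
    return pd.DataFrame(rows)


def write_coherence(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")
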