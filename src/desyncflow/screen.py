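"""Per-transcript mixed-model screen for disruption by mistimed sleep.

Each probe's log2 expression is modelled as

    y ~ condition + time_bin + condition:time_bin + (1 | participant)

where ``time_bin`` is the cortisol-phase-aligned sampling time discretised
into eight equal-frequency bins pooled across the cohort. Two tests are run
per probe as likelihood-ratio tests of nested maximum-likelihood fits
against a chi-square reference:

* main effect of sleep condition (additive model vs. drop-condition, 1 df)
  — an overall up/down shift in expression between conditions;
* condition x time-bin interaction (full vs. additive, n_bins - 1 df)
  — a change in the shape/timing of the temporal profile.

p-values are Benjamini-Hochberg adjusted across probes separately within
each test family; a probe is "affected" when either adjusted p is below
alpha. No rhythmicity detection is performed: the screen asks only whether
level or temporal profile changed, not whether profiles are rhythmic.

The random-intercept model is fitted by profiled maximum likelihood: for a
fixed variance ratio lambda = sigma_u^2 / sigma_e^2 the GLS estimate and the
profiled log-likelihood are available in closed form (the marginal
covariance is block-diagonal with a rank-one block per participant), leaving
a one-dimensional bounded optimisation over log(lambda). The boundary
lambda = 0 (no participant variance) reduces smoothly to OLS, so all-null
probes are handled without numerical failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import OUT_OF_PHASE, PERIOD_H, ExpressionDataset

DEFAULT_N_BINS = 8
#: probes missing more than this fraction of observations are excluded
MAX_MISSING_FRACTION = 0.2


# ---------------------------------------------------------------------------
# Phase alignment and binning
# ---------------------------------------------------------------------------

@dataclass
class AlignedDesign:
    """Per-sample design for the screen: participant, condition, time bin."""

    table: pd.DataFrame          # sample_id, participant_id, condition,
                                 # aligned_time_h, time_bin (1..n_bins)
    n_bins: int
    binning: str                 # "quantile" or "width"

    def __post_init__(self):
        bins = self.table["time_bin"]
        if bins.isna().any() or (bins < 1).any() or (bins > self.n_bins).any():
            raise ValueError("every observation must fall in exactly one bin")


def align_and_bin(data: ExpressionDataset, cortisol_fits,
                  n_bins: int = DEFAULT_N_BINS,
                  binning: str = "quantile") -> AlignedDesign:
    """Express sample times relative to each participant's cortisol peak.

    ``cortisol_fits`` maps participant_id -> CosinorFit (or peak hour).
    Alignment uses the participant's in-phase cortisol peak for both
    conditions, since the cortisol rhythm persists under misalignment:
    aligned_time_h = (clock_time_h - peak_time_h) mod 24. The pooled
    aligned times are then discretised into ``n_bins`` categories, by
    default equal-frequency (rank-based, so occupancy differs by at most
    one between bins); ``binning="width"`` uses equal-width 24/n_bins-h
    bins instead.
    """
    peaks = {}
    for pid, fit in dict(cortisol_fits).items():
        peak = fit if np.isscalar(fit) else fit.peak_time_h
        if not np.isfinite(peak):
            raise ValueError(f"participant {pid}: undefined cortisol peak")
        peaks[pid] = float(peak)

    table = data.samples[["sample_id", "participant_id", "condition",
                          "clock_time_h"]].copy()
    missing = set(table["participant_id"]) - set(peaks)
    if missing:
        raise ValueError(f"no cortisol fit for participant(s): {sorted(missing)}")
    peak_arr = table["participant_id"].map(peaks).to_numpy()
    aligned = (table["clock_time_h"].to_numpy() - peak_arr) % PERIOD_H
    table["aligned_time_h"] = aligned

    if binning == "quantile":
        # rank-based equal-frequency assignment; ties broken by order
        order = np.argsort(aligned, kind="stable")
        ranks = np.empty(len(aligned), dtype=int)
        ranks[order] = np.arange(len(aligned))
        table["time_bin"] = ranks * n_bins // len(aligned) + 1
    elif binning == "width":
        width = PERIOD_H / n_bins
        table["time_bin"] = np.minimum(aligned // width, n_bins - 1).astype(int) + 1
    else:
        raise ValueError(f"unknown binning mode {binning!r}")
    return AlignedDesign(table=table, n_bins=n_bins, binning=binning)


# ---------------------------------------------------------------------------
# Profiled-ML random-intercept engine
# ---------------------------------------------------------------------------

class _RandomInterceptML:
    """Maximum-likelihood fit of y = X b + u_group + e via profiling.

    For lambda = sigma_u^2/sigma_e^2 the group-blocked marginal covariance
    inverts by the Sherman-Morrison identity, V_g^{-1} = I - w_g J with
    w_g = lambda / (1 + lambda * n_g), so GLS cross-products need only
    per-group column sums. sigma_e^2 is profiled out analytically and
    log(lambda) is optimised on a bounded interval.
    """

    #: search bounds for log(lambda)
    LOG_LAMBDA_BOUNDS = (-12.0, 12.0)

    def __init__(self, group_idx: np.ndarray, n_groups: int):
        self.gidx = group_idx
        self.n_groups = n_groups
        self.counts = np.bincount(group_idx, minlength=n_groups).astype(float)

    def _profile(self, lam: float, y: np.ndarray, X: np.ndarray):
        n, p = X.shape
        w = lam / (1.0 + lam * self.counts)
        gsX = np.zeros((self.n_groups, p))
        np.add.at(gsX, self.gidx, X)
        gsy = np.bincount(self.gidx, weights=y, minlength=self.n_groups)
        XtVi = X.T @ X - (gsX * w[:, None]).T @ gsX
        XtViy = X.T @ y - gsX.T @ (w * gsy)
        beta = np.linalg.solve(XtVi, XtViy)
        r = y - X @ beta
        gsr = np.bincount(self.gidx, weights=r, minlength=self.n_groups)
        rss = float(r @ r - w @ gsr**2)
        s2 = rss / n
        if s2 <= 0:   # perfectly fitted response
            return math.inf, beta, 0.0
        ll = (-0.5 * n * math.log(2 * math.pi * s2)
              - 0.5 * float(np.sum(np.log1p(lam * self.counts)))
              - 0.5 * n)
        return ll, beta, s2

    def fit(self, y: np.ndarray, X: np.ndarray):
        """Return (loglik, beta, lambda_hat, converged)."""
        ll0, beta0, _ = self._profile(0.0, y, X)

        def neg(theta):
            return -self._profile(math.exp(theta), y, X)[0]

        res = minimize_scalar(neg, bounds=self.LOG_LAMBDA_BOUNDS,
                              method="bounded", options={"xatol": 1e-8})
        if np.isfinite(res.fun) and -res.fun > ll0:
            lam = math.exp(res.x)
            ll, beta, _ = self._profile(lam, y, X)
        else:
            lam, ll, beta = 0.0, ll0, beta0
        converged = bool(np.isfinite(ll))
        return ll, beta, lam, converged


def _design_matrices(design: AlignedDesign):
    """Full / additive / bin-only fixed-effect design matrices (treatment coding)."""
    table = design.table
    n = len(table)
    cond = (table["condition"] == OUT_OF_PHASE).to_numpy(dtype=float)[:, None]
    bins = table["time_bin"].to_numpy() - 1
    B = np.eye(design.n_bins)[bins][:, 1:]                # drop reference bin
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, cond, B, cond * B])
    X_add = np.hstack([ones, cond, B])
    X_bin = np.hstack([ones, B])
    return X_full, X_add, X_bin


@dataclass(frozen=True)
class ProbeTestResult:
    p_main: float
    p_interaction: float
    n_obs: int
    lambda_full: float
    converged: bool


def screen_probe(y, design: AlignedDesign, engine=None,
                 designs=None, group_idx=None) -> ProbeTestResult:
    """Likelihood-ratio tests for one probe's condition and interaction effects.

    Missing observations are dropped for this probe only (pairwise-drop
    policy). ``engine``/``designs``/``group_idx`` allow :func:`screen_all`
    to reuse precomputed structures across probes.
    """
    y = np.asarray(y, dtype=float)
    table = design.table
    if designs is None:
        designs = _design_matrices(design)
    if group_idx is None:
        pids = table["participant_id"]
        group_idx = pids.map({p: i for i, p in enumerate(pids.unique())}).to_numpy()

    mask = np.isfinite(y)
    if mask.sum() < len(y):
        y = y[mask]
        designs = tuple(X[mask] for X in designs)
        group_idx = group_idx[mask]
        groups, group_idx = np.unique(group_idx, return_inverse=True)
        engine = _RandomInterceptML(group_idx, len(groups))
    elif engine is None:
        engine = _RandomInterceptML(group_idx, group_idx.max() + 1)

    sub = table.loc[mask] if mask.sum() < len(mask) else table
    if sub["participant_id"].nunique() < 2:
        raise ValueError("screen needs >= 2 participants")
    if sub["condition"].nunique() < 2:
        raise ValueError("both sleep conditions must be observed")

    X_full, X_add, X_bin = designs
    ll_full, _, lam, c1 = engine.fit(y, X_full)
    ll_add, _, _, c2 = engine.fit(y, X_add)
    ll_bin, _, _, c3 = engine.fit(y, X_bin)
    converged = c1 and c2 and c3

    df_int = X_full.shape[1] - X_add.shape[1]
    df_main = X_add.shape[1] - X_bin.shape[1]
    if converged:
        p_int = float(chi2.sf(max(0.0, 2 * (ll_full - ll_add)), df_int))
        p_main = float(chi2.sf(max(0.0, 2 * (ll_add - ll_bin)), df_main))
    else:
        p_int = p_main = np.nan
    return ProbeTestResult(p_main=p_main, p_interaction=p_int,
                           n_obs=len(y), lambda_full=lam, converged=converged)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def screen_all(data: ExpressionDataset, design: AlignedDesign,
               alpha: float = 0.05) -> pd.DataFrame:
    """Run the per-probe screen across the whole matrix with BH correction.

    Returns a DataFrame with one row per probe: raw and BH-adjusted p-values
    for the main effect and interaction, and the ``affected`` label
    (either BH p < alpha). Probes with more than 20% missing observations
    are excluded (reported with NaN p-values and ``excluded=True``).
    """
    table = design.table
    order = {s: i for i, s in enumerate(data.values.columns)}
    col_idx = table["sample_id"].map(order)
    if col_idx.isna().any():
        raise ValueError("design refers to samples absent from the matrix")
    Y = data.values.to_numpy()[:, col_idx.to_numpy()]

    pids = table["participant_id"]
    group_idx = pids.map({p: i for i, p in enumerate(pids.unique())}).to_numpy()
    engine = _RandomInterceptML(group_idx, group_idx.max() + 1)
    designs = _design_matrices(design)

    rows = []
    n_excluded = 0
    for gi, probe in enumerate(data.values.index):
        y = Y[gi]
        frac_missing = 1.0 - np.isfinite(y).mean()
        if frac_missing > MAX_MISSING_FRACTION:
            n_excluded += 1
            rows.append({"probe_id": probe, "p_main_raw": np.nan,
                         "p_interaction_raw": np.nan, "n_obs": int(np.isfinite(y).sum()),
                         "converged": False, "excluded": True})
            continue
        r = screen_probe(y, design, engine=engine, designs=designs,
                        group_idx=group_idx)
        rows.append({"probe_id": probe, "p_main_raw": r.p_main,
                     "p_interaction_raw": r.p_interaction, "n_obs": r.n_obs,
                     "converged": r.converged, "excluded": False})
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} probes with > "
                      f"{MAX_MISSING_FRACTION:.0%} missing observations",
                      stacklevel=2)

    res = pd.DataFrame(rows)
    res.insert(1, "gene_symbol", res["probe_id"].map(data.gene_symbols).fillna(""))
    res["p_main_bh"] = benjamini_hochberg(res["p_main_raw"].to_numpy())
    res["p_interaction_bh"] = benjamini_hochberg(res["p_interaction_raw"].to_numpy())
    res["affected"] = ((res["p_main_bh"] < alpha)
                       | (res["p_interaction_bh"] < alpha)).fillna(False)
    return res


# ---------------------------------------------------------------------------
# Overlap with a gene set
# ---------------------------------------------------------------------------

def overlap_with_set(results: pd.DataFrame, gene_set, alpha: float = 0.05) -> dict:
    """Partition of a gene set's probes by how they were affected.

    Counts probes whose gene belongs to the set, split into main-effect
    only / interaction only / both / affected / not affected, plus the
    affected fraction.
    """
    members = gene_set.members if hasattr(gene_set, "members") else set(gene_set)
    members = {str(m).upper() for m in members}
    in_set = results[results["gene_symbol"].isin(members)]
    main = in_set["p_main_bh"] < alpha
    inter = in_set["p_interaction_bh"] < alpha
    n_aff = int((main | inter).sum())
    return {
        "set_name": getattr(gene_set, "name", ""),
        "n_probes_in_set": len(in_set),
        "n_affected": n_aff,
        "n_main_only": int((main & ~inter).sum()),
        "n_interaction_only": int((inter & ~main).sum()),
        "n_both": int((main & inter).sum()),
        "fraction_affected": n_aff / len(in_set) if len(in_set) else np.nan,
    }


def write_screen_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_screen_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str})
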