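"""Phase alignment, the mixed-model screen, and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from desyncflow import (
    CORTISOL, IN_PHASE, OUT_OF_PHASE, align_and_bin, benjamini_hochberg,
    overlap_with_set, screen_all, screen_probe,
)
from desyncflow.io import GeneSet
from desyncflow.screen import _RandomInterceptML
from desyncflow.cosinor import fit_cohort


# ---------------------------------------------------------------------------
# align_and_bin
# ---------------------------------------------------------------------------

def _cortisol_peaks(study):
    fits = fit_cohort([s for s in study.hormones
                       if s.analyte == CORTISOL and s.condition == IN_PHASE])
    return {f.participant_id: f for f in fits}


def test_alignment_at_peak_is_zero(small_study):
    design = align_and_bin(small_study.expression, _cortisol_peaks(small_study))
    peaks = {p: f.peak_time_h for p, f in _cortisol_peaks(small_study).items()}
    t = small_study.expression.samples
    expected = (t["clock_time_h"].to_numpy()
                - t["participant_id"].map(peaks).to_numpy()) % 24
    np.testing.assert_allclose(design.table["aligned_time_h"], expected)


def test_quantile_bins_are_balanced(small_study):
    """Equal-frequency bins: occupancy differs by at most 1."""
    design = align_and_bin(small_study.expression, _cortisol_peaks(small_study))
    counts = design.table["time_bin"].value_counts()
    assert set(counts.index) == set(range(1, 9))
    assert counts.max() - counts.min() <= 1


def test_quantile_bins_match_sort_and_slice(small_study):
    design = align_and_bin(small_study.expression, _cortisol_peaks(small_study))
    t = design.table
    order = np.argsort(t["aligned_time_h"].to_numpy(), kind="stable")
    expected = np.empty(len(t), dtype=int)
    expected[order] = np.arange(len(t)) * 8 // len(t) + 1
    np.testing.assert_array_equal(t["time_bin"].to_numpy(), expected)


def test_width_bins(small_study):
    design = align_and_bin(small_study.expression, _cortisol_peaks(small_study),
                           binning="width")
    t = design.table
    expected = np.minimum(t["aligned_time_h"] // 3.0, 7).astype(int) + 1
    np.testing.assert_array_equal(t["time_bin"], expected)


def test_missing_cortisol_fit_is_error(small_study):
    peaks = _cortisol_peaks(small_study)
    peaks.pop(next(iter(peaks)))
    with pytest.raises(ValueError, match="no cortisol fit"):
        align_and_bin(small_study.expression, peaks)


# ---------------------------------------------------------------------------
# random-intercept ML engine vs statsmodels MixedLM
# ---------------------------------------------------------------------------

def test_profiled_ml_matches_statsmodels():
    """ML log-likelihood and LRT agree with MixedLM on well-posed data."""
    import warnings
    from statsmodels.regression.mixed_linear_model import MixedLM

    rng = np.random.default_rng(8)
    n_g, per = 15, 14
    gidx = np.repeat(np.arange(n_g), per)
    x = rng.normal(size=n_g * per)
    y = (rng.normal(0, 0.8, n_g)[gidx] + 0.4 * x
         + rng.normal(0, 0.5, n_g * per))
    X = np.column_stack([np.ones_like(x), x])
    engine = _RandomInterceptML(gidx, n_g)
    ll, beta, lam, conv = engine.fit(y, X)
    assert conv
    df = pd.DataFrame({"y": y, "x": x, "g": gidx})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = MixedLM.from_formula("y ~ x", groups="g", data=df).fit(reml=False)
    assert abs(ll - m.llf) < 1e-6
    np.testing.assert_allclose(beta, m.fe_params.to_numpy(), atol=1e-5)


def test_engine_handles_zero_group_variance():
    """Pure-noise data sits at the lambda = 0 boundary without failure."""
    rng = np.random.default_rng(1)
    gidx = np.repeat(np.arange(10), 10)
    y = rng.normal(size=100)
    X = np.ones((100, 1))
    ll, _, lam, conv = _RandomInterceptML(gidx, 10).fit(y, X)
    assert conv
    assert lam < 0.2


# ---------------------------------------------------------------------------
# screen_probe
# ---------------------------------------------------------------------------

def _null_design(study):
    return align_and_bin(study.expression, _cortisol_peaks(study))


def test_symmetric_probe_gives_unit_pvalues(small_study):
    """y depending only on (participant, bin) -> LRT statistics exactly 0."""
    design = _null_design(small_study)
    t = design.table
    pid_code = t["participant_id"].astype("category").cat.codes.to_numpy()
    # non-additive function of (participant, bin), identical across conditions
    y = np.sin(pid_code * 1.7) * t["time_bin"].to_numpy() + 0.3 * pid_code
    r = screen_probe(y, design)
    # the condition terms are exactly zero by symmetry; the LRT statistic is
    # zero up to the variance-ratio optimiser's tolerance
    assert r.p_main > 0.999
    assert r.p_interaction > 0.999


def test_level_shift_detected_as_main_effect(small_study):
    design = _null_design(small_study)
    t = design.table
    rng = np.random.default_rng(0)
    y = rng.normal(0, 0.05, len(t)) + (t["condition"] == OUT_OF_PHASE) * 1.0
    r = screen_probe(y.to_numpy(), design)
    assert r.p_main < 1e-20
    assert r.p_interaction > 1e-4   # no profile-shape change


def test_condition_label_swap_leaves_pvalues_unchanged(small_study):
    design = _null_design(small_study)
    rng = np.random.default_rng(4)
    y = rng.normal(size=len(design.table))
    r1 = screen_probe(y, design)
    swapped = design.table.copy()
    swapped["condition"] = swapped["condition"].map(
        {IN_PHASE: OUT_OF_PHASE, OUT_OF_PHASE: IN_PHASE})
    design2 = type(design)(table=swapped, n_bins=design.n_bins,
                           binning=design.binning)
    r2 = screen_probe(y, design2)
    assert abs(r1.p_main - r2.p_main) < 1e-8
    assert abs(r1.p_interaction - r2.p_interaction) < 1e-8


def test_missing_values_dropped_pairwise(small_study):
    design = _null_design(small_study)
    rng = np.random.default_rng(2)
    y = rng.normal(size=len(design.table))
    y[:5] = np.nan
    r = screen_probe(y, design)
    assert r.n_obs == len(y) - 5
    assert np.isfinite(r.p_main)


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

def _bh_brute(p):
    """Textbook step-up with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_spec_example():
    np.testing.assert_allclose(
        benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])),
        [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(benjamini_hochberg(np.array([0.031])), [0.031])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_brute_force_and_is_monotone(ps):
    p = np.array(ps)
    adj = benjamini_hochberg(p)
    np.testing.assert_allclose(adj, _bh_brute(p), atol=1e-12)
    assert np.all(adj >= p - 1e-12)
    # idempotent on already-adjusted values' ordering
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# screen_all + overlap
# ---------------------------------------------------------------------------

def test_screen_recovers_truth_classes(small_study):
    design = _null_design(small_study)
    res = screen_all(small_study.expression, design)
    truth = small_study.truth.probes.set_index("probe_id")
    merged = res.set_index("probe_id").join(truth[["probe_class", "affected"]],
                                            rsuffix="_true")
    # unaffected classes rarely flagged; changed classes mostly flagged
    null_like = merged[merged.probe_class.isin(["FLAT", "CIRCADIAN_LOCKED"])]
    assert null_like["affected"].mean() <= 0.2
    disrupted = merged[merged.probe_class.isin(
        ["SLEEPWAKE_DRIVEN", "DISRUPTED_AMP", "DISRUPTED_MEAN"])]
    assert disrupted["affected"].mean() >= 0.6


def test_overlap_with_set(small_study):
    design = _null_design(small_study)
    res = screen_all(small_study.expression, design)
    empty = overlap_with_set(res, GeneSet("none", "", frozenset({"ZZZ"})))
    assert empty["n_affected"] == 0 and empty["n_probes_in_set"] == 0

    platform = GeneSet("all", "", frozenset(small_study.expression.platform_genes()))
    everything = overlap_with_set(res, platform)
    assert everything["n_probes_in_set"] == len(res)
    parts = (everything["n_main_only"] + everything["n_interaction_only"]
             + everything["n_both"])
    assert parts == everything["n_affected"]

    truth = small_study.truth.probes
    truth_affected_targets = truth[truth.is_target & truth.affected]
    got = overlap_with_set(res, small_study.target_set)
    # recovered count within a generous binomial band of the truth count
    assert abs(got["n_affected"] - len(truth_affected_targets)) <= 5


def test_probes_with_excess_missingness_are_excluded(small_study):
    ds = small_study.expression
    values = ds.values.copy()
    probe = values.index[0]
    values.loc[probe, values.columns[: int(0.3 * values.shape[1])]] = np.nan
    ds2 = type(ds)(values=values, gene_symbols=ds.gene_symbols.copy(),
                   samples=ds.samples.copy())
    design = _null_design(small_study)
    with pytest.warns(UserWarning, match="excluded 1 probes"):
        res = screen_all(ds2, design)
    row = res.set_index("probe_id").loc[probe]
    assert row["excluded"]
    assert not row["affected"]
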