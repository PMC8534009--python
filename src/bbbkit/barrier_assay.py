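"""TEER and solute-permeability quantification for Transwell barriers.

The apparent permeability of a monolayer-on-insert follows from the
accumulation of tracer in the lower (abluminal) chamber:

    P = (dC_L/dt) * V_L / (C_U * S)                                 (i)

with C_U the upper-chamber driving concentration, V_L the lower-chamber
volume and S the membrane area. Because the insert itself resists
transport, the monolayer-only permeability is obtained from the series-
barrier relation

    1/P_total = 1/P_barrier + 1/P_insert                            (ii)

TEER values are background-corrected ((total - blank filter) resistance)
and area-normalised to Ohm * cm^2.

Two practical corrections are applied to the raw sampled series before
the slope in (i) is taken. First, draw-and-replace sampling dilutes the
lower chamber; the cumulative correction restores what the concentration
would have been without draws. Second, over a long assay the upper
chamber measurably depletes, so by default the transferred mass is
regressed against the integral of the *measured* driving gradient
(reconstructed from the data by mass balance) rather than against time;
this reduces exactly to (i) when the sink condition C_L << C_U ~ const
holds, and stays unbiased when it does not. ``assume_sink=True`` selects
the plain slope-versus-time estimator.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats

from .datatypes import AssayGeometry, PermeabilityResult, TeerRecord, TranswellSeries

__all__ = [
    "corrected_cumulative",
    "permeability_total",
    "permeability_from_slope",
    "permeability_ibbb",
    "teer_area",
    "wilcoxon_signed_rank",
    "group_ratio",
    "compare_groups",
]

#: warn when the corrected lower concentration exceeds this fraction of
#: the initial upper concentration (sink assumption degrading)
SINK_WARN_FRACTION = 0.10


def corrected_cumulative(series: TranswellSeries, correct: bool = True) -> np.ndarray:
    """Cumulative lower-chamber concentration, corrected for sampling dilution.

    Each 50 uL draw replaced by fresh medium removes a fraction
    f = V_sample/V_L of the accumulated tracer; the corrected series

        C_corr(t_k) = C_L(t_k) + f * sum_{j<k} C_L(t_j)

    restores the cumulative concentration that would have been observed
    without draws. With ``correct=False`` the input is returned unchanged
    (sensitivity mode).
    """
    if series.times_min.size < 3:
        raise ValueError("need at least 3 timepoints")
    c = series.lower_conc_um
    if not correct:
        return c.copy()
    f = series.geometry.sample_volume_ml / series.geometry.lower_volume_ml
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c + f * prior


def _reconstructed_gradient_integral(series: TranswellSeries,
                                     cumulative: np.ndarray) -> np.ndarray:
    """S * integral of the driving gradient (C_U - C_L) dt, per timepoint.

    The upper-chamber concentration at each sampling time is recovered
    from tracer mass balance: everything missing from the upper chamber
    is either in the lower chamber or was withdrawn, both of which the
    sampled series records. The integral uses the trapezoid rule on each
    interval with post-draw lower concentrations as left endpoints.
    """
    g = series.geometry
    t_s = series.times_min * 60.0
    c_lo = series.lower_conc_um
    f = g.sample_volume_ml / g.lower_volume_ml
    m0 = g.upper_conc_um * g.upper_volume_ml
    withdrawn = g.sample_volume_ml * np.concatenate([[0.0], np.cumsum(c_lo)[:-1]])
    c_up = (m0 - g.lower_volume_ml * c_lo - withdrawn) / g.upper_volume_ml
    grad_pre = c_up - c_lo                # gradient just before each draw
    grad_post = c_up - c_lo * (1.0 - f)   # gradient just after each draw
    dt = np.diff(t_s)
    incr = 0.5 * (grad_post[:-1] + grad_pre[1:]) * dt
    return g.membrane_area_cm2 * np.concatenate([[0.0], np.cumsum(incr)])


def permeability_total(series: TranswellSeries, correct: bool = True,
                       assume_sink: bool = False) -> PermeabilityResult:
    """Apparent permeability (monolayer + insert) of a sampled series.

    Reports the least-squares slope of the corrected cumulative
    concentration versus time (uM/s) and its r^2. ``p_total`` is that
    slope scaled by V_L/(C_U*S) when ``assume_sink`` is set, and
    otherwise the slope of transferred mass against the reconstructed
    driving-gradient integral (see module docstring), which corrects for
    upper-chamber depletion.
    """
    g = series.geometry
    if g.upper_conc_um <= 0:
        raise ValueError("upper concentration must be positive")
    cum = corrected_cumulative(series, correct=correct)
    t_s = series.times_min * 60.0
    fit = stats.linregress(t_s, cum)
    slope, r2 = fit.slope, fit.rvalue ** 2

    if cum.max() > SINK_WARN_FRACTION * g.upper_conc_um:
        warnings.warn(
            "corrected lower concentration exceeds "
            f"{SINK_WARN_FRACTION:.0%} of the upper concentration; the "
            "constant-driving-force assumption is degrading", stacklevel=2)

    if assume_sink:
        p_total = slope * g.lower_volume_ml / (g.upper_conc_um * g.membrane_area_cm2)
    else:
        x = _reconstructed_gradient_integral(series, cum)
        y = g.lower_volume_ml * cum
        fit_g = stats.linregress(x, y)
        p_total, r2 = fit_g.slope, fit_g.rvalue ** 2
    return PermeabilityResult(p_total=float(p_total), slope_um_per_s=float(slope),
                              slope_r2=float(r2))


def permeability_from_slope(slope_um_per_s: float, geom: AssayGeometry) -> float:
    """Direct evaluation of P = slope * V_L / (C_U * S)."""
    if geom.upper_conc_um <= 0:
        raise ValueError("upper concentration must be positive")
    return slope_um_per_s * geom.lower_volume_ml / (geom.upper_conc_um * geom.membrane_area_cm2)


def permeability_ibbb(p_total: float, p_insert: float) -> float:
    """Monolayer-only permeability from the series-barrier relation.

    1/p_total = 1/p_barrier + 1/p_insert  =>  p_barrier = 1/(1/p_total - 1/p_insert).
    An insert no more permeable than the whole assembly means the
    monolayer added no resistance and the model is violated.
    """
    if p_total <= 0:
        raise ValueError("p_total must be positive")
    if np.isinf(p_insert):
        return p_total
    if p_total >= p_insert:
        raise ValueError(
            "p_total >= p_insert: series-barrier model violated "
            "(monolayer adds no measurable resistance)")
    return 1.0 / (1.0 / p_total - 1.0 / p_insert)


def teer_area(total_ohm: float, blank_ohm: float, area_cm2: float) -> TeerRecord:
    """Background-corrected, area-normalised TEER: (total - blank) * area."""
    if area_cm2 <= 0:
        raise ValueError("membrane area must be positive")
    if blank_ohm < 0:
        raise ValueError("blank resistance must be non-negative")
    if total_ohm <= blank_ohm:
        raise ValueError("total <= blank resistance: no barrier formed")
    net = (total_ohm - blank_ohm) * area_cm2
    return TeerRecord(total_ohm, blank_ohm, area_cm2, net)


def wilcoxon_signed_rank(paired_diffs) -> tuple[float, float]:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties in |difference| receive mid-ranks.
    For n <= 20 the p-value is exact over all 2^n sign assignments,
    computed by subset-sum dynamic programming over the (doubled, hence
    integer) ranks: p = P(|W+ - E[W+]| >= |w_obs - E[W+]|). Beyond n = 20
    the normal approximation from scipy is used.

    Returns (W+, p) where W+ is the sum of ranks of positive differences.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n > 20:
        res = stats.wilcoxon(d, correction=True, mode="approx")
        return w_plus, float(res.pvalue)

    ranks2 = np.rint(2 * ranks).astype(int)  # mid-ranks doubled -> integers
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        dist[r:] += dist[:-r].copy() if r > 0 else 0
    dist /= 2.0 ** n
    mean2 = total / 2.0
    obs_dev = abs(2 * w_plus - mean2)
    devs = np.abs(np.arange(total + 1) - mean2)
    p = float(dist[devs >= obs_dev - 1e-9].sum())
    return w_plus, min(p, 1.0)


def group_ratio(del_mean: float, wt_mean: float, mode: str = "percent") -> float:
    """Patient/control ratio as a percentage or a fold change."""
    if wt_mean <= 0:
        raise ValueError("control mean must be positive")
    if mode == "percent":
        return 100.0 * del_mean / wt_mean
    if mode == "fold":
        return del_mean / wt_mean
    raise ValueError("mode must be 'percent' or 'fold'")


def compare_groups(del_values, wt_values, paired: bool = True) -> dict:
    """Group summary for a patient-vs-control comparison.

    Means, standard errors, percent and fold ratios of means, a per-pair
    mean fold (when paired), and the exact Wilcoxon signed-rank p on the
    paired differences (or on unpaired differences of means when
    ``paired=False``, in which case no test is run and p is None).
    """
    dv = np.asarray(del_values, dtype=float)
    wv = np.asarray(wt_values, dtype=float)
    out = {
        "del_mean": float(dv.mean()),
        "del_se": float(dv.std(ddof=1) / np.sqrt(dv.size)) if dv.size > 1 else 0.0,
        "wt_mean": float(wv.mean()),
        "wt_se": float(wv.std(ddof=1) / np.sqrt(wv.size)) if wv.size > 1 else 0.0,
        "n_del": int(dv.size),
        "n_wt": int(wv.size),
    }
    out["percent_of_wt"] = group_ratio(out["del_mean"], out["wt_mean"], "percent")
    out["fold_of_wt"] = group_ratio(out["del_mean"], out["wt_mean"], "fold")
    if paired:
        if dv.size != wv.size:
            raise ValueError("paired comparison requires equal group sizes")
        out["fold_per_pair_mean"] = float(np.mean(dv / wv))
        diffs = dv - wv
        if np.any(diffs != 0):
            w, p = wilcoxon_signed_rank(diffs)
            out["wilcoxon_w"] = w
            out["wilcoxon_p"] = p
        else:
            out["wilcoxon_w"] = None
            out["wilcoxon_p"] = 1.0
    else:
        out["wilcoxon_p"] = None
    return out
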