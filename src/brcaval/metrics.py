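"""Weighted calibration, discrimination and risk-stratification statistics.

All statistics accept per-woman sampling weights (inverse inclusion
probabilities); with unit weights they reduce exactly to their classical
unweighted definitions.

Calibration: the expected/observed case ratio E/O (E = sum w*p,
O = sum w*y) with a log-normal CI using the Poisson-type standard error
sqrt(sum w^2 y)/O, and the calibration slope — the coefficient of
logit(predicted risk) in a weighted logistic regression of the observed
outcome, 1 under perfect calibration.  Discrimination: the weighted AUC
(probability a random case outranks a random non-case, ties half) with a
stratified-bootstrap CI, and weighted Harrell's C over comparable
time-to-event pairs with a grouped-jackknife CI.  Stratification:
proportions below clinical 5-year-risk thresholds, the negative
predictive value below each threshold, and the fraction of incident
cases captured by the top predicted-risk half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError, InvalidParameterError

DEFAULT_THRESHOLDS = (0.0165, 0.03, 0.05)
_Z95 = float(stats.norm.ppf(0.975))


def _as_arrays(pred, outcome, weights):
    p = np.asarray(pred, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, float)
    if not (p.shape == y.shape == w.shape):
        raise InvalidParameterError("pred, outcome, weights length mismatch")
    if (w <= 0).any():
        raise InvalidParameterError("weights must be positive")
    return p, y, w


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class EOResult:
    expected: float
    observed: float
    ratio: float
    ci: tuple[float, float]


def expected_observed_ratio(pred, outcome, weights=None) -> EOResult:
    """Weighted expected/observed case ratio with a log-normal 95% CI."""
    p, y, w = _as_arrays(pred, outcome, weights)
    e = float(np.sum(w * p))
    o = float(np.sum(w * y))
    if o == 0:
        raise DegenerateDataError("no observed cases: E/O undefined")
    ratio = e / o
    se_log = float(np.sqrt(np.sum(w ** 2 * y))) / o
    ci = (ratio * np.exp(-_Z95 * se_log), ratio * np.exp(_Z95 * se_log))
    return EOResult(expected=e, observed=o, ratio=ratio, ci=ci)


def calibration_slope(pred, outcome, weights=None,
                      clip: float = 1e-6) -> tuple[float, tuple[float, float]]:
    """Coefficient of logit(pred) in a weighted logistic fit of outcome.

    Predictions are clipped to [clip, 1-clip] before the logit.  The Wald
    CI uses the robust (HC1) covariance when weights are supplied.
    """
    p, y, w = _as_arrays(pred, outcome, weights)
    p = np.clip(p, clip, 1.0 - clip)
    x = np.log(p / (1.0 - p))
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant predictions: slope undefined")
    if y.min() == y.max():
        raise DegenerateDataError("single-class outcome: slope undefined")
    design = np.column_stack([np.ones_like(x), x])
    model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(cov_type="HC1" if weights is not None else "nonrobust")
    slope = float(res.params[1])
    se = float(res.bse[1])
    return slope, (slope - _Z95 * se, slope + _Z95 * se)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    targets = np.asarray(q) * cum[-1]
    idx = np.searchsorted(cum, targets, side="left")
    return v[np.minimum(idx, v.size - 1)]


def quintile_calibration(pred, outcome, weights=None, n_bins: int = 5,
                         weighted_quantiles: bool = True) -> pd.DataFrame:
    """Per-bin E, O and E/O at (weighted) quantile bins of predicted risk.

    Ties on a bin edge are assigned to the lower bin.  Per-bin expected
    counts partition the overall E exactly.
    """
    p, y, w = _as_arrays(pred, outcome, weights)
    if p.size < n_bins:
        raise InvalidParameterError("fewer observations than bins")
    qs = np.arange(1, n_bins) / n_bins
    inner = _weighted_quantile(p, w if weighted_quantiles else
                               np.ones_like(w), qs)
    bin_idx = np.searchsorted(inner, p, side="left")
    rows = []
    for b in range(n_bins):
        mask = bin_idx == b
        e = float(np.sum(w[mask] * p[mask]))
        o = float(np.sum(w[mask] * y[mask]))
        if o > 0:
            se_log = float(np.sqrt(np.sum(w[mask] ** 2 * y[mask]))) / o
            ratio = e / o
            ci_lo, ci_hi = (ratio * np.exp(-_Z95 * se_log),
                            ratio * np.exp(_Z95 * se_log))
        else:
            ratio, ci_lo, ci_hi = np.nan, np.nan, np.nan
        lo = float(p[mask].min()) if mask.any() else np.nan
        hi = float(p[mask].max()) if mask.any() else np.nan
        rows.append({"bin": b + 1, "pred_min": lo, "pred_max": hi,
                     "n": int(mask.sum()), "expected": e, "observed": o,
                     "eo_ratio": ratio, "ci_low": ci_lo, "ci_high": ci_hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def _weighted_auc_point(p: np.ndarray, y: np.ndarray,
                        w: np.ndarray) -> float:
    order = np.argsort(p, kind="mergesort")
    p, y, w = p[order], y[order], w[order]
    wn = w * (1.0 - y)
    wc = w * y
    new_group = np.r_[True, p[1:] != p[:-1]]
    gid = np.cumsum(new_group) - 1
    g_wn = np.bincount(gid, weights=wn)
    g_wc = np.bincount(gid, weights=wc)
    below = np.cumsum(g_wn) - g_wn
    total_c, total_n = g_wc.sum(), g_wn.sum()
    if total_c == 0 or total_n == 0:
        raise DegenerateDataError("AUC needs both cases and non-cases")
    conc = float(np.sum(g_wc * (below + 0.5 * g_wn)))
    return conc / (total_c * total_n)


def auc(pred, outcome, weights=None, n_boot: int = 2000,
        seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Weighted AUC with a stratified-bootstrap percentile 95% CI.

    The point estimate is the weighted probability that a random case's
    prediction exceeds a random non-case's, counting ties as half.
    ``n_boot=0`` skips the CI (returned as NaN bounds).
    """
    p, y, w = _as_arrays(pred, outcome, weights)
    value = _weighted_auc_point(p, y, w)
    if n_boot <= 0:
        return value, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(case_idx, size=case_idx.size, replace=True),
            rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)])
        reps[b] = _weighted_auc_point(p[idx], y[idx], w[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return value, (float(lo), float(hi))


class _Fenwick:
    """Prefix-sum tree over prediction ranks (weights as values)."""

    def __init__(self, size: int):
        self.tree = np.zeros(size + 1)

    def add(self, i: int, value: float) -> None:
        i += 1
        while i < self.tree.size:
            self.tree[i] += value
            i += i & (-i)

    def prefix(self, i: int) -> float:
        """Sum of values at ranks 0..i-1."""
        s = 0.0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def _concordance_sums(p, t, e, w) -> tuple[float, float, float]:
    """(concordant, pred-tied, comparable) weighted pair sums.

    A pair is comparable when the strictly earlier time belongs to an
    event; it is concordant when that earlier-event member has the higher
    predicted risk; prediction ties count half.  Pair weight is the
    product of member weights.  O(n log n) via a Fenwick tree over
    prediction ranks, processing times in decreasing order so the tree
    always holds the strictly-later members.
    """
    _, rank = np.unique(p, return_inverse=True)
    n_ranks = int(rank.max()) + 1
    order = np.argsort(-t, kind="mergesort")
    tree = _Fenwick(n_ranks)
    conc = tied = comp = 0.0
    total_in_tree = 0.0
    i = 0
    n = p.size
    while i < n:
        j = i
        while j < n and t[order[j]] == t[order[i]]:
            j += 1
        for k in order[i:j]:          # query before inserting the tie group
            if e[k]:
                below = tree.prefix(int(rank[k]))          # lower pred
                at = tree.prefix(int(rank[k]) + 1) - below  # tied pred
                later = total_in_tree
                conc += w[k] * below   # earlier event, higher pred
                tied += w[k] * at
                comp += w[k] * later
        for k in order[i:j]:
            tree.add(int(rank[k]), w[k])
            total_in_tree += w[k]
        i = j
    return conc, tied, comp


def harrell_c(pred, time, event, weights=None, n_groups: int = 50,
              seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Weighted Harrell's C-index with a grouped-jackknife 95% CI.

    ``time`` is the follow-up time from the landmark; ``event`` flags the
    BC events.  ``n_groups=0`` skips the CI.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    w = np.ones_like(p) if weights is None else np.asarray(weights, float)
    if not (p.shape == t.shape == e.shape == w.shape):
        raise InvalidParameterError("input length mismatch")
    if (t <= 0).any():
        raise InvalidParameterError("times must be positive")
    conc, tied, comp = _concordance_sums(p, t, e, w)
    if comp == 0:
        raise DegenerateDataError("no comparable pairs: C undefined")
    value = (conc + 0.5 * tied) / comp
    if n_groups <= 0:
        return value, (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    g = min(n_groups, p.size)
    assignment = rng.permutation(p.size) % g
    leave_out = np.empty(g)
    for k in range(g):
        keep = assignment != k
        ck, tk, mk = _concordance_sums(p[keep], t[keep], e[keep], w[keep])
        leave_out[k] = (ck + 0.5 * tk) / mk if mk > 0 else value
    se = float(np.sqrt((g - 1) / g * np.sum((leave_out - leave_out.mean())
                                            ** 2)))
    return value, (value - _Z95 * se, value + _Z95 * se)


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

def top_fraction_capture(pred, outcome, weights=None,
                         fraction: float = 0.5) -> float:
    """Weighted share of incident cases in the top predicted-risk
    ``fraction`` of women."""
    p, y, w = _as_arrays(pred, outcome, weights)
    total_cases = np.sum(w * y)
    if total_cases == 0:
        raise DegenerateDataError("no cases: capture undefined")
    order = np.argsort(-p, kind="mergesort")
    cum = np.cumsum(w[order])
    top = cum <= fraction * cum[-1] + 1e-12
    return float(np.sum((w * y)[order][top]) / total_cases)


def risk_stratification(pred, outcome, weights=None,
                        thresholds=DEFAULT_THRESHOLDS,
                        age_at_entry=None, gene=None,
                        age_cutpoints=(30.0, 50.0)) -> dict:
    """Threshold table, NPV and top-half case capture.

    Per threshold: the weighted proportion of women with predicted risk
    below it, the negative predictive value among them, and (when
    ``age_at_entry``/``gene`` are given) the composition of the
    below-threshold group by entry-age band and gene.
    """
    p, y, w = _as_arrays(pred, outcome, weights)
    thresholds = tuple(thresholds)
    if any(not 0 < t < 1 for t in thresholds) or \
            any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidParameterError("thresholds must strictly increase "
                                    "within (0, 1)")
    total_w = float(np.sum(w))
    rows = []
    for thr in thresholds:
        below = p < thr
        w_below = float(np.sum(w[below]))
        row = {"threshold": thr, "prop_below": w_below / total_w}
        if w_below > 0:
            row["npv"] = 1.0 - float(np.sum(w[below] * y[below])) / w_below
        else:
            row["npv"] = np.nan
        if age_at_entry is not None and w_below > 0:
            age = np.asarray(age_at_entry, dtype=float)
            edges = (-np.inf,) + tuple(age_cutpoints) + (np.inf,)
            for lo, hi in zip(edges[:-1], edges[1:]):
                label = f"age_{'' if lo == -np.inf else int(lo)}" \
                        f"_{'' if hi == np.inf else int(hi)}".strip("_")
                in_band = below & (age >= lo) & (age < hi)
                row[f"frac_below_{label}"] = \
                    float(np.sum(w[in_band])) / w_below
        if gene is not None:
            genes = np.asarray(gene)
            for g in np.unique(genes):
                sub = genes == g
                denom = float(np.sum(w[sub]))
                row[f"prop_below_{g}"] = \
                    float(np.sum(w[sub & below])) / denom if denom else np.nan
        rows.append(row)
    try:
        capture = top_fraction_capture(p, y, w, 0.5)
    except DegenerateDataError:
        capture = np.nan
    return {"table": pd.DataFrame(rows), "top_half_capture": capture}


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class VariantMetrics:
    """One variant x subgroup row of the validation report."""

    variant: str
    subgroup: str
    n: int
    expected: float
    observed: float
    eo_ratio: float
    eo_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    harrell_c: float
    c_ci: tuple[float, float]
    quintiles: pd.DataFrame


@dataclass
class ValidationReport:
    """Full validation output across predictor variants and subgroups."""

    rows: list[VariantMetrics]
    stratification: dict | None = None
    metadata: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "variant": r.variant, "subgroup": r.subgroup, "n": r.n,
                "E": r.expected, "O": r.observed,
                "EO_ratio": r.eo_ratio,
                "EO_lo": r.eo_ci[0], "EO_hi": r.eo_ci[1],
                "slope": r.slope,
                "slope_lo": r.slope_ci[0], "slope_hi": r.slope_ci[1],
                "AUC": r.auc, "AUC_lo": r.auc_ci[0], "AUC_hi": r.auc_ci[1],
                "C": r.harrell_c, "C_lo": r.c_ci[0], "C_hi": r.c_ci[1]})
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        out = {"metadata": self.metadata,
               "rows": self.summary_frame().to_dict(orient="records"),
               "quintiles": {f"{r.variant}|{r.subgroup}":
                             r.quintiles.to_dict(orient="records")
                             for r in self.rows}}
        if self.stratification is not None:
            out["stratification"] = {
                "table": self.stratification["table"]
                .to_dict(orient="records"),
                "top_half_capture": self.stratification["top_half_capture"]}
        return out


def evaluate_predictions(prepared: pd.DataFrame, risks: pd.DataFrame,
                         weights=None, subgroups_by_gene: bool = True,
                         thresholds=DEFAULT_THRESHOLDS,
                         stratify_variant: str | None = None,
                         n_boot: int = 2000, jackknife_groups: int = 50,
                         seed: int = 0) -> ValidationReport:
    """Compute the full report for a prepared cohort and predicted risks.

    ``risks`` has one column per variant, aligned row-wise with
    ``prepared``.  Weights (if given) are per-woman sampling weights.
    The stratification block is computed for ``stratify_variant`` (by
    default the last variant column).
    """
    y = prepared["outcome_5y"].to_numpy(dtype=float)
    t = prepared["time_from_landmark"].to_numpy(dtype=float)
    ev = (prepared["event"] == "BC").to_numpy()
    w = None if weights is None else np.asarray(weights, dtype=float)
    genes = prepared["gene"].astype(str).to_numpy()
    groups = [("all", np.ones(len(prepared), dtype=bool))]
    if subgroups_by_gene:
        groups += [(g, genes == g) for g in sorted(np.unique(genes))]
    rows = []
    for vi, variant in enumerate(risks.columns):
        p = risks[variant].to_numpy(dtype=float)
        for gi, (label, mask) in enumerate(groups):
            sub_w = None if w is None else w[mask]
            eo = expected_observed_ratio(p[mask], y[mask], sub_w)
            try:
                slope, slope_ci = calibration_slope(p[mask], y[mask], sub_w)
            except DegenerateDataError:
                slope, slope_ci = np.nan, (np.nan, np.nan)
            sub_seed = seed * 1000 + vi * 10 + gi
            a, a_ci = auc(p[mask], y[mask], sub_w, n_boot=n_boot,
                          seed=sub_seed)
            c, c_ci = harrell_c(p[mask], t[mask], ev[mask], sub_w,
                                n_groups=jackknife_groups, seed=sub_seed)
            rows.append(VariantMetrics(
                variant=variant, subgroup=label, n=int(mask.sum()),
                expected=eo.expected, observed=eo.observed,
                eo_ratio=eo.ratio, eo_ci=eo.ci, slope=slope,
                slope_ci=slope_ci, auc=a, auc_ci=a_ci,
                harrell_c=c, c_ci=c_ci,
                quintiles=quintile_calibration(p[mask], y[mask], sub_w)))
    target = stratify_variant or risks.columns[-1]
    strat = risk_stratification(
        risks[target].to_numpy(dtype=float), y, w, thresholds=thresholds,
        age_at_entry=prepared["baseline_age"].to_numpy(dtype=float),
        gene=genes)
    return ValidationReport(rows=rows, stratification=strat,
                            metadata={"stratify_variant": target})
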