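"""Repeated-measures differential analysis of discretized-RPM counts.

The inferential unit is one fragment (or one isodecoder) measured in
every participant at paired timepoints.  Discretized RPM values are
modelled as negative-binomial counts with a log-linear condition effect
and a per-participant intercept:

    y_it ~ NB(mu_it, theta),   Var = mu + mu^2 / theta
    log mu_it = b0 + b_cond * x_it + u_i,   u_i ~ N(0, sigma^2)

The random-intercept likelihood is maximized by Gauss-Hermite
quadrature; when that fit fails, the model falls back to conditional
fixed participant intercepts (flagged ``converged=False``), and to a
paired sign test when even that is degenerate.  The condition effect is
tested with a two-sided Wald test and reported as FC = exp(b_cond).
P-values are deliberately not adjusted for multiple testing: closely
related fragments of one tRNA are strongly dependent, and standard
corrections assuming independence would inflate type-II error.  An
optional Benjamini-Hochberg column is emitted for reference but never
used for calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .classify import discretize_rpm
from .mapping import ExpressionTable, TIMEPOINTS

__all__ = [
    "DiffResult",
    "nb_repeated_test",
    "differential_analysis",
    "isodecoder_aggregate",
    "fold_change",
    "group_contrast",
    "paired_wilcoxon_onesided",
    "WilcoxonResult",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DiffResult:
    unit_id: str
    contrast: str
    log_fold_change: float
    fold_change: float
    p_value: float
    mean_rpm: dict[str, float]
    n_participants: int
    converged: bool
    method: str  # "random_intercept" | "fixed_intercepts" | "sign_test" | "undefined"


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB log-pmf in mean/dispersion form (Var = mu + mu^2/theta)."""
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


class _RandomInterceptNB:
    """Marginal likelihood of the NB random-intercept model via
    Gauss-Hermite quadrature over the participant effect."""

    def __init__(self, y, x, participant_idx, n_participants, n_nodes=21):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.idx = np.asarray(participant_idx)
        self.n_part = n_participants
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        self.nodes = nodes * _SQRT2          # N(0,1) scaled abscissae
        self.log_w = np.log(weights) - 0.5 * math.log(math.pi)

    def negloglik(self, params: np.ndarray) -> float:
        b0, bc, log_theta, log_sigma = params
        theta = math.exp(min(log_theta, 30.0))
        sigma = math.exp(log_sigma)
        eta = b0 + bc * self.x
        # (n_obs, K) log-pmf at each quadrature node
        mu = np.exp(np.clip(eta[:, None] + sigma * self.nodes[None, :], -30, 30))
        lp = _nb_logpmf(self.y[:, None], mu, theta)
        per_part = np.zeros((self.n_part, lp.shape[1]))
        np.add.at(per_part, self.idx, lp)
        ll = special.logsumexp(per_part + self.log_w[None, :], axis=1).sum()
        return -ll if np.isfinite(ll) else 1e12


def _wald_p(beta: float, se: float, df: float) -> float:
    """Two-sided Wald p with a t reference on ``df`` degrees of freedom.

    With ~15 participants the normal reference is anti-conservative
    because the dispersion and random-intercept variance are estimated;
    a t reference on (participants - 1) df is the usual small-sample
    correction for mixed-model Wald tests.
    """
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    return 2.0 * sps.t.sf(abs(beta) / se, df)


def _fit_fixed_intercepts(y, x, idx, n_part, df):
    """Conditional fallback: NB regression with participant dummies."""
    import statsmodels.api as sm

    dummies = np.eye(n_part)[idx][:, 1:]  # first participant absorbed by const
    X = np.column_stack([np.ones_like(x, dtype=float), x, dummies])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        res = model.fit(disp=0, maxiter=200)
    beta = float(res.params[1])
    se = float(res.bse[1])
    return beta, _wald_p(beta, se, df)


def nb_repeated_test(
    counts: pd.DataFrame,
    unit_id: str = "",
    contrast: str = "",
    n_nodes: int = 21,
) -> DiffResult:
    """Fit the NB repeated-measures model to one unit.

    ``counts`` needs columns ``participant``, ``condition`` (exactly two
    levels; the first level sorted is the reference, FC is level2/level1
    when ``contrast`` is empty, otherwise the contrast string "A_vs_B"
    dictates A as numerator) and ``count`` (non-negative integers --
    discretized RPM).  Requires >= 3 participants with both conditions.
    """
    df = counts.copy()
    y = df["count"].to_numpy()
    if not np.allclose(y, np.round(y)) or np.any(y < 0):
        raise ValueError(
            "counts must be non-negative integers; discretize RPM first "
            "(see nitrna.classify.discretize_rpm)"
        )
    y = y.astype(float)

    levels = sorted(df["condition"].unique())
    if contrast:
        num, _, den = contrast.partition("_vs_")
        if {num, den} != set(levels):
            raise ValueError(
                f"contrast {contrast!r} does not match condition levels {levels}"
            )
    else:
        den, num = levels[0], levels[-1]
        contrast = f"{num}_vs_{den}"
    x = (df["condition"] == num).to_numpy(dtype=float)

    participants = sorted(df["participant"].unique())
    both = [
        p for p in participants
        if df.loc[df["participant"] == p, "condition"].nunique() == 2
    ]
    mean_rpm = {
        lev: float(y[df["condition"].to_numpy() == lev].mean()) for lev in levels
    }
    if len(both) < 3:
        raise ValueError("need >= 3 participants observed in both conditions")
    if y.sum() == 0:
        return DiffResult(unit_id, contrast, float("nan"), float("nan"),
                          float("nan"), mean_rpm, len(both), False, "undefined")

    part_index = {p: i for i, p in enumerate(participants)}
    idx = df["participant"].map(part_index).to_numpy()
    n_part = len(participants)

    mean_num = y[x == 1].mean()
    mean_den = y[x == 0].mean()
    b0_start = math.log(mean_den + 0.5)
    bc_start = math.log((mean_num + 0.5) / (mean_den + 0.5))
    start = np.array([b0_start, bc_start, 0.0, math.log(0.5)])
    bounds = [(-30, 30), (-15, 15), (-8, 12), (-8, 3)]

    model = _RandomInterceptNB(y, x, idx, n_part, n_nodes=n_nodes)
    try:
        res = optimize.minimize(
            model.negloglik, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300},
        )
        beta = float(res.x[1])
        # central differences: forward-difference Hessians visibly
        # understate the curvature here and inflate the type-I rate
        from statsmodels.tools.numdiff import approx_hess3

        hess = approx_hess3(res.x, model.negloglik)
        cov = np.linalg.pinv(hess)
        se = math.sqrt(max(float(cov[1, 1]), 0.0))
        p = _wald_p(beta, se, len(both) - 1)
        if res.success and np.isfinite(p):
            return DiffResult(unit_id, contrast, beta, math.exp(beta), p,
                              mean_rpm, len(both), True, "random_intercept")
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        pass

    try:
        beta, p = _fit_fixed_intercepts(y, x, idx, n_part, len(both) - 1)
        if np.isfinite(p):
            return DiffResult(unit_id, contrast, beta, math.exp(beta), p,
                              mean_rpm, len(both), False, "fixed_intercepts")
    except Exception:
        pass

    # last resort: paired sign test on participant means
    diffs = []
    for p_id in both:
        sub = df[df["participant"] == p_id]
        d = (sub.loc[sub["condition"] == num, "count"].mean()
             - sub.loc[sub["condition"] == den, "count"].mean())
        if d != 0:
            diffs.append(d)
    if not diffs:
        return DiffResult(unit_id, contrast, 0.0, 1.0, 1.0, mean_rpm,
                          len(both), False, "sign_test")
    k = sum(d > 0 for d in diffs)
    p = float(sps.binomtest(k, len(diffs), 0.5).pvalue)
    beta = math.log((mean_num + 0.5) / (mean_den + 0.5))
    return DiffResult(unit_id, contrast, beta, math.exp(beta), p, mean_rpm,
                      len(both), False, "sign_test")


def differential_analysis(
    table: ExpressionTable,
    contrast: tuple[str, str] = ("Sugar", "Healthy"),
    unit_ids: Sequence[str] | None = None,
    n_nodes: int = 21,
    add_bh_column: bool = True,
) -> pd.DataFrame:
    """Run nb_repeated_test on every fragment of an expression table.

    ``contrast`` is (numerator, denominator) timepoints.  Only
    participants with both timepoints contribute.  Returns one row per
    unit with model and descriptive fold changes; an optional BH-FDR
    column is appended for reference only.
    """
    num, den = contrast
    participants = table.complete_participants((num, den))
    cols_num = [table.sample_index(p, num) for p in participants]
    cols_den = [table.sample_index(p, den) for p in participants]
    disc = discretize_rpm(table.rpm)
    ids = unit_ids if unit_ids is not None else table.sequences

    rows = []
    for i, uid in enumerate(ids):
        long = pd.DataFrame(
            {
                "participant": participants * 2,
                "condition": [num] * len(participants) + [den] * len(participants),
                "count": np.concatenate([disc[i, cols_num], disc[i, cols_den]]),
            }
        )
        try:
            r = nb_repeated_test(long, unit_id=uid,
                                 contrast=f"{num}_vs_{den}", n_nodes=n_nodes)
        except ValueError:
            continue
        rows.append(
            {
                "unit_id": uid,
                "contrast": r.contrast,
                "log_fold_change": r.log_fold_change,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "descriptive_fc": fold_change(
                    table.rpm[i, cols_num], table.rpm[i, cols_den]
                ),
                f"mean_rpm_{num}": float(table.rpm[i, cols_num].mean()),
                f"mean_rpm_{den}": float(table.rpm[i, cols_den].mean()),
                "n_participants": r.n_participants,
                "converged": r.converged,
                "method": r.method,
            }
        )
    out = pd.DataFrame(rows)
    if add_bh_column and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        bh = np.full(len(out), np.nan)
        if mask.any():
            bh[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        out["bh_fdr_reference_only"] = bh
    return out


def isodecoder_aggregate(
    table: ExpressionTable,
    annotations: pd.DataFrame,
    display_min_rpm: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum fragment RPM per isodecoder per sample.

    Returns (isodecoder x sample RPM table with a ``display`` flag for
    mean RPM >= ``display_min_rpm``, subtype x isodecoder composition of
    total RPM).  The display flag gates reporting only; every
    isodecoder stays in the analysis.
    """
    rpm = pd.DataFrame(
        table.rpm, index=table.sequences,
        columns=[s.sample_id for s in table.samples],
    )
    ann = annotations.set_index("sequence")
    rpm = rpm.join(ann[["isodecoder", "subtype"]])
    by_iso = rpm.groupby("isodecoder").sum(numeric_only=True)
    by_iso["mean_rpm"] = by_iso.mean(axis=1)
    by_iso["display"] = by_iso["mean_rpm"] >= display_min_rpm
    composition = (
        rpm.assign(total=rpm.select_dtypes("number").sum(axis=1))
        .groupby(["isodecoder", "subtype"])["total"].sum().unstack(fill_value=0.0)
    )
    return by_iso, composition


def fold_change(
    a: np.ndarray, b: np.ndarray, pseudocount: float = 0.5
) -> float:
    """Descriptive fold change (mean_a + eps) / (mean_b + eps).

    The pseudocount guards empty conditions; the model-based FC from
    nb_repeated_test needs none and is reported alongside.
    """
    return float(
        (np.mean(a) + pseudocount) / (np.mean(b) + pseudocount)
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    exact: bool
    undefined: bool = False


def _exact_signed_rank_tail(ranks2: np.ndarray, w2_obs: int) -> float:
    """P(W+ >= observed) under random signs, via the generating function
    of doubled (hence integer, tie-averaged) ranks."""
    total = int(ranks2.sum())
    coeff = np.zeros(total + 1)
    coeff[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(coeff)
        shifted[r:] = coeff[: total + 1 - r]
        coeff = coeff + shifted
    tail = coeff[w2_obs:].sum()
    return float(tail / 2 ** len(ranks2))


def paired_wilcoxon_onesided(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """One-sided paired Wilcoxon signed-rank test for x > y.

    Zero differences are dropped (Wilcoxon convention); an all-zero
    vector is flagged undefined.  Exact tail probability (supporting
    tied ranks) for n <= ``exact_max_n``, normal approximation with tie
    and continuity corrections above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(float("nan"), float("nan"), 0, False, True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _exact_signed_rank_tail(ranks2, w2)
        return WilcoxonResult(w_plus, p, n, True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return WilcoxonResult(w_plus, float(sps.norm.sf(z)), n, False)


def group_contrast(
    diff_results: pd.DataFrame,
    table: ExpressionTable,
    annotations: pd.DataFrame,
    motility: pd.DataFrame | None = None,
    alpha: float = 0.05,
    correlation: str = "pearson",
) -> dict:
    """Sugar-sensitive vs other group trajectories relative to Start.

    Groups are (sugar-sensitive | other) x (nuclear | mitochondrial),
    where sugar-sensitive means p < alpha and FC > 1 in the
    Sugar-vs-Healthy contrast.  For each group: the per-participant
    mean RPM at each timepoint, one-sided paired Wilcoxon contrasts of
    each later timepoint vs Start, and -- when a motility table with
    columns (participant, timepoint, motility) is supplied -- the
    correlation between per-participant (Sugar - Start) changes in group
    mean RPM and in motility.
    """
    ann = annotations.set_index("sequence")
    sig = diff_results.set_index("unit_id")
    sensitive = set(
        sig.index[(sig["p_value"] < alpha) & (sig["fold_change"] > 1)]
    )
    participants = table.complete_participants()
    cols = {
        t: [table.sample_index(p, t) for p in participants] for t in TIMEPOINTS
    }
    out: dict = {"groups": {}, "participants": participants}
    for origin in ("nuclear", "mitochondrial"):
        for label, member in (("sugar_sensitive", True), ("other", False)):
            seqs = [
                s for s in table.sequences
                if ann.loc[s, "origin"] == origin and ((s in sensitive) == member)
            ]
            key = f"{label}_{origin}"
            if not seqs:
                out["groups"][key] = None
                continue
            rows = [table.sequences.index(s) for s in seqs]
            # per-participant mean RPM over the group's fragments
            means = {t: table.rpm[np.ix_(rows, cols[t])].mean(axis=0) for t in TIMEPOINTS}
            entry = {
                "n_fragments": len(seqs),
                "participant_means": {t: means[t].tolist() for t in TIMEPOINTS},
                "contrast_vs_start": {},
            }
            for t in ("Healthy", "Sugar"):
                w = paired_wilcoxon_onesided(means[t], means["Start"])
                entry["contrast_vs_start"][t] = {
                    "p_value": w.p_value, "undefined": w.undefined,
                }
            if motility is not None:
                mot = motility.set_index(["participant", "timepoint"])["motility"]
                try:
                    dm = np.array(
                        [mot[(p, "Sugar")] - mot[(p, "Start")] for p in participants]
                    )
                except KeyError:
                    dm = None
                if dm is not None:
                    dg = means["Sugar"] - means["Start"]
                    if correlation == "spearman":
                        r, p = sps.spearmanr(dg, dm)
                    else:
                        r, p = sps.pearsonr(dg, dm)
                    entry["motility_correlation"] = {"r": float(r), "p_value": float(p)}
            out["groups"][key] = entry
    return out
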