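"""Ratio construction and empirical-Bayes moderated testing.

The ratio statistic for an isoform pair (a, b) is the per-sample difference
of generalized-log abundances, glog2(a) − glog2(b).  Because any additive
per-sample offset (global loading, normalization shifts) cancels in the
difference, ratio rows are self-normalizing.  Each ratio row (or each
protein row, for single-protein differential expression) is fit with
ordinary least squares against a design matrix; residual variances are
shrunk toward a common prior by the empirical-Bayes moment method
(scaled inverse-chi-square prior on the true variances), and moderated
t-statistics with d0 + d degrees of freedom are computed per row.
Multiple testing is controlled with Benjamini–Hochberg FDR.

Pairs are additionally filtered on the minor isoform fraction (MIF),
min(a, b) / (a + b) averaged over samples, which removes pairs where one
member is present only at trace levels and the ratio is dominated by noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .pairing import IsoformPair

__all__ = [
    "DesignSpec",
    "ModelFit",
    "build_design",
    "compute_ratio_matrix",
    "compute_mif",
    "fit_linear_model",
    "trigamma_inverse",
    "squeeze_variances",
    "moderated_t",
    "bh_adjust",
    "classify_pairs",
    "ratio_test",
    "single_protein_de",
    "cross_tabulate_pair_de",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """A per-sample design matrix and the contrast of interest.

    ``matrix`` is samples × coefficients with an intercept column;
    categorical factors use treatment coding with the first-appearing level
    as reference, so a coefficient like ``ageP1`` estimates P1 − E17
    directly.  ``contrast`` names the coefficient tested.
    """

    samples: list[str]
    matrix: pd.DataFrame
    contrast: str
    formula: str = ""

    def __post_init__(self) -> None:
        X = self.matrix.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            aliased = _aliased_columns(self.matrix)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{X.shape[1]} columns); aliased columns: {aliased}")
        if self.contrast not in self.matrix.columns:
            raise ValueError(
                f"contrast {self.contrast!r} is not a design coefficient; "
                f"available: {list(self.matrix.columns)}")

    @property
    def contrast_vector(self) -> np.ndarray:
        return (self.matrix.columns == self.contrast).astype(float)


def _aliased_columns(matrix: pd.DataFrame) -> list[str]:
    """Identify columns that do not increase the design rank (QR sweep)."""
    aliased = []
    kept: list[str] = []
    for col in matrix.columns:
        trial = matrix[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) == len(kept):
            aliased.append(col)
        else:
            kept.append(col)
    return aliased


def build_design(design_table: pd.DataFrame, formula: str = "~ condition",
                 contrast: str | None = None) -> DesignSpec:
    """Build a main-effects design matrix from a sample table and formula.

    The formula uses R-style ``~ term1 + term2`` syntax restricted to main
    effects (a leading response name such as ``expression`` is ignored).
    String columns are treatment-coded against their first-appearing level;
    numeric columns enter as-is.  The default contrast is the first
    non-intercept coefficient of the first term.
    """
    rhs = formula.split("~", 1)[-1]
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    if not terms:
        raise ValueError(f"formula has no terms: {formula!r}")
    samples = design_table["sample"].tolist()
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(samples))}
    first_term_coefs: list[str] = []
    for ti, term in enumerate(terms):
        if term not in design_table.columns:
            raise ValueError(f"formula term {term!r} is not a design column")
        values = design_table[term]
        if pd.api.types.is_numeric_dtype(values):
            # numeric covariate enters linearly
            cols[term] = values.to_numpy(dtype=float)
            if ti == 0:
                first_term_coefs.append(term)
        else:
            levels = list(dict.fromkeys(values.astype(str)))
            for level in levels[1:]:
                name = f"{term}{level}"
                cols[name] = (values.astype(str) == level).to_numpy(dtype=float)
                if ti == 0:
                    first_term_coefs.append(name)
    matrix = pd.DataFrame(cols, index=samples)
    if contrast is None:
        if not first_term_coefs:
            raise ValueError("cannot infer a default contrast from the formula")
        contrast = first_term_coefs[0]
    return DesignSpec(samples=samples, matrix=matrix, contrast=contrast,
                      formula=formula)


def compute_ratio_matrix(glog_quant: pd.DataFrame,
                         pairs: Sequence[IsoformPair]) -> pd.DataFrame:
    """Pairwise glog-ratio matrix: row = pair, entry = glog2(a) − glog2(b).

    An entry is missing whenever either member is missing in that sample.
    Pairs with a member absent from the matrix entirely are dropped with a
    warning.
    """
    rows = {}
    dropped = []
    for pair in pairs:
        if pair.accession_a not in glog_quant.index or \
                pair.accession_b not in glog_quant.index:
            dropped.append(pair.pair_id)
            continue
        rows[pair.pair_id] = (glog_quant.loc[pair.accession_a]
                              - glog_quant.loc[pair.accession_b])
    if dropped:
        warnings.warn(f"{len(dropped)} pairs dropped: member not in matrix "
                      f"(e.g. {dropped[:3]})")
    if not rows:
        out = pd.DataFrame(columns=glog_quant.columns)
    else:
        out = pd.DataFrame(rows).T
        out.columns = glog_quant.columns
    out.index.name = "pair_id"
    return out


def compute_mif(raw_quant: pd.DataFrame, pair: IsoformPair,
                samples: Sequence[str] | None = None,
                mode: str = "pooled") -> float:
    """Minor isoform fraction of a pair: mean over samples of min(a,b)/(a+b).

    Computed on raw (pre-log) abundances over samples where both members
    are quantified.  ``mode="pooled"`` (default) averages over all such
    samples; ``mode="per_condition_min"`` takes the minimum of per-condition
    means (requires ``samples`` to be a mapping condition → sample list).
    Returns NaN when no sample has a positive pair total.
    """
    if mode == "per_condition_min":
        if not isinstance(samples, Mapping):
            raise ValueError("per_condition_min mode needs a condition→samples mapping")
        vals = [compute_mif(raw_quant, pair, samples=list(s), mode="pooled")
                for s in samples.values()]
        vals = [v for v in vals if np.isfinite(v)]
        return min(vals) if vals else float("nan")
    if mode != "pooled":
        raise ValueError(f"unknown MIF mode: {mode!r}")
    cols = list(samples) if samples is not None else list(raw_quant.columns)
    a = raw_quant.loc[pair.accession_a, cols].astype(float)
    b = raw_quant.loc[pair.accession_b, cols].astype(float)
    total = a + b
    ok = total.notna() & (total > 0)
    if not ok.any():
        return float("nan")
    frac = np.minimum(a[ok], b[ok]) / total[ok]
    return float(frac.mean())


@dataclass
class ModelFit:
    """Per-row OLS estimates plus empirical-Bayes moderation state."""

    coefficients: pd.Series        # contrast estimate per row
    stdev_unscaled: pd.Series      # sqrt(c' (X'X)^-1 c) per row
    sigma2: pd.Series              # residual variance s^2 per row
    df_residual: pd.Series         # residual degrees of freedom per row
    contrast: str
    df_prior: float = float("nan")
    s2_prior: float = float("nan")
    s2_post: pd.Series | None = None


def fit_linear_model(Y: pd.DataFrame, design: DesignSpec) -> ModelFit:
    """Row-wise ordinary least squares of a matrix against a design.

    Rows may contain missing values; each distinct missingness pattern is
    fit on its complete samples (the design must remain full rank on that
    subset).  Rows with residual df < 1 or with a rank-deficient reduced
    design are flagged untestable (all-NaN estimates).
    """
    if list(Y.columns) != design.samples:
        Y = Y[design.samples]
    X_full = design.matrix.to_numpy(dtype=float)
    c = design.contrast_vector
    values = Y.to_numpy(dtype=float)
    n_rows = values.shape[0]

    coef = np.full(n_rows, np.nan)
    se_unscaled = np.full(n_rows, np.nan)
    s2 = np.full(n_rows, np.nan)
    dfres = np.zeros(n_rows)

    masks = pd.DataFrame(np.isfinite(values))
    for pattern, idx in masks.groupby(list(masks.columns)).groups.items():
        present = np.asarray(pattern, dtype=bool)
        rows = np.asarray(idx, dtype=int)
        X = X_full[present]
        n_obs = int(present.sum())
        p = X.shape[1]
        if n_obs < p or np.linalg.matrix_rank(X) < p:
            continue
        xtx_inv = np.linalg.inv(X.T @ X)
        H = xtx_inv @ X.T
        sub = values[np.ix_(rows, np.flatnonzero(present))]
        betas = sub @ H.T                        # rows × p
        resid = sub - betas @ X.T
        d = n_obs - p
        coef[rows] = betas @ c
        se_unscaled[rows] = np.sqrt(c @ xtx_inv @ c)
        dfres[rows] = d
        if d >= 1:
            s2[rows] = (resid ** 2).sum(axis=1) / d

    untestable = int(np.sum(~np.isfinite(coef)))
    if untestable:
        logger.info("%d rows untestable (insufficient observations)", untestable)
    idx = Y.index
    return ModelFit(
        coefficients=pd.Series(coef, index=idx),
        stdev_unscaled=pd.Series(se_unscaled, index=idx),
        sigma2=pd.Series(s2, index=idx),
        df_residual=pd.Series(dfres, index=idx),
        contrast=design.contrast,
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone Newton iteration.

    Started from the asymptotic inverse 1/x (trigamma(y) ~ 1/y for large y).
    Returns +inf for non-positive x (no finite solution) and raises no
    error on non-convergence — the caller treats that as d0 = inf.
    """
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = max(1.0 / x, 1e-8)
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif / y) < tol:
            return float(y)
    warnings.warn("trigamma inversion did not converge; treating as infinite df")
    return float("inf")


def squeeze_variances(s2: np.ndarray | pd.Series, df: np.ndarray | pd.Series,
                      min_rows: int = 20) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-row variances.

    Assumes true variances follow a scaled inverse-chi-square prior with
    ``d0`` degrees of freedom and location ``s0^2``, so observed ``s^2``
    are scaled F.  Moment estimation on log variances: with
    ``e = log(s^2) − digamma(d/2) + log(d/2)``, the excess of var(e) over
    the mean of trigamma(d/2) estimates trigamma(d0/2), inverted by Newton
    iteration, and ``s0^2`` follows from the mean of e.  Returns
    ``(d0, s0_sq, posterior variances)`` where the posterior per row is
    ``(d0*s0^2 + d*s^2) / (d0 + d)``.

    With fewer than ``min_rows`` usable rows the test falls back to the
    unmoderated variances (d0 = 0) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df >= 1) & (s2 > 0)
    if ok.sum() < min_rows:
        warnings.warn(f"only {int(ok.sum())} rows with positive variance; "
                      "falling back to unmoderated test (d0 = 0)")
        return 0.0, float("nan"), s2.copy()

    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    tri_excess = e_var - np.mean(special.polygamma(1, d / 2.0))
    if tri_excess > 0:
        d0 = 2.0 * trigamma_inverse(tri_excess)
    else:
        d0 = float("inf")
    if np.isfinite(d0):
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        s0_sq = float(np.exp(e_mean))

    post = np.array(s2, dtype=float)
    have = np.isfinite(s2) & (df >= 1)
    if np.isfinite(d0):
        post[have] = (d0 * s0_sq + df[have] * s2[have]) / (d0 + df[have])
    else:
        post[have] = s0_sq
    return float(d0), s0_sq, post


def ebayes(fit: ModelFit, min_rows: int = 20) -> ModelFit:
    """Attach empirical-Bayes posterior variances to a fit (in place)."""
    d0, s0_sq, post = squeeze_variances(fit.sigma2.to_numpy(),
                                        fit.df_residual.to_numpy(),
                                        min_rows=min_rows)
    fit.df_prior = d0
    fit.s2_prior = s0_sq
    fit.s2_post = pd.Series(post, index=fit.sigma2.index)
    return fit


def moderated_t(fit: ModelFit) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values per row.

    ``t = coef / (sqrt(s2_post) * stdev_unscaled)`` on ``d0 + d`` degrees
    of freedom; infinite prior df gives the normal reference.  With
    ``d0 = 0`` this reduces exactly to the ordinary per-row t-test.
    Rows with zero posterior variance or zero unscaled se are flagged NaN.
    """
    if fit.s2_post is None:
        ebayes(fit)
    denom = np.sqrt(fit.s2_post.to_numpy()) * fit.stdev_unscaled.to_numpy()
    coef = fit.coefficients.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, coef / denom, np.nan)
    df_total = fit.df_prior + fit.df_residual.to_numpy()
    p = np.full_like(t, np.nan)
    finite = np.isfinite(t)
    if np.isfinite(fit.df_prior):
        p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total[finite])
    else:
        p[finite] = 2.0 * stats.norm.sf(np.abs(t[finite]))
    return pd.DataFrame({"logFC": fit.coefficients, "t": t, "p": p,
                         "df_total": df_total}, index=fit.coefficients.index)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept).

    NaN entries are passed through and do not count toward the number of
    tests.
    """
    arr = np.asarray(p, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(arr, np.nan)
    if vals.size:
        out[finite] = multipletests(vals, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def classify_pairs(results: pd.DataFrame, fdr: float = 0.01,
                   min_abs_lfc: float = 0.5, min_mif: float = 0.05) -> pd.DataFrame:
    """Flag significant isoform shifts and record failure reasons.

    A pair is significant iff adjusted p < ``fdr`` AND |logFC| ≥
    ``min_abs_lfc`` AND average MIF ≥ ``min_mif``.  The ``reason`` column
    lists every failed criterion (``fdr``, ``lfc``, ``mif``, ``untested``)
    for non-significant pairs.
    """
    out = results.copy()
    reasons = []
    sig = []
    for _, row in out.iterrows():
        r = []
        if not np.isfinite(row["adj_p"]):
            r.append("untested")
        elif row["adj_p"] >= fdr:
            r.append("fdr")
        if not np.isfinite(row["logFC"]) or abs(row["logFC"]) < min_abs_lfc:
            r.append("lfc")
        if not np.isfinite(row["mif"]) or row["mif"] < min_mif:
            r.append("mif")
        reasons.append(";".join(r))
        sig.append(not r)
    out["significant"] = sig
    out["reason"] = reasons
    return out


def ratio_test(
    glog_quant: pd.DataFrame,
    raw_quant: pd.DataFrame,
    pairs: Sequence[IsoformPair],
    design: DesignSpec,
    fdr: float = 0.01,
    min_abs_lfc: float = 0.5,
    min_mif: float = 0.05,
    complete_case: bool = True,
    df_prior: float | None = None,
) -> pd.DataFrame:
    """Full ratio-testing pipeline for a list of isoform pairs.

    Builds the glog-ratio matrix, applies the completeness filter
    (complete-case by default: a pair is tested only if both members are
    quantified in every sample), fits the design, moderates variances,
    computes moderated t / BH-adjusted p, attaches the average MIF, and
    classifies significance.  ``df_prior`` forces the prior degrees of
    freedom (0 disables moderation); by default it is estimated.
    """
    ratio = compute_ratio_matrix(glog_quant, pairs)
    pair_by_id = {p.pair_id: p for p in pairs}
    n_before = len(ratio)
    if complete_case:
        ratio = ratio.dropna(axis=0)
    logger.info("completeness filter: %d of %d pairs testable", len(ratio), n_before)

    fit = fit_linear_model(ratio, design)
    if df_prior is None:
        ebayes(fit)
    else:
        fit.df_prior = df_prior
        fit.s2_prior = float("nan")
        fit.s2_post = fit.sigma2.copy()  # d0 = 0: no shrinkage
        if df_prior != 0:
            raise ValueError("df_prior may only be forced to 0 (unmoderated) "
                             "or left None (estimated)")
    res = moderated_t(fit)
    res["adj_p"] = bh_adjust(res["p"])
    mif = {pid: compute_mif(raw_quant, pair_by_id[pid],
                            samples=list(raw_quant.columns))
           for pid in res.index}
    res["mif"] = pd.Series(mif)
    meta = pd.DataFrame({
        "accession_a": {p.pair_id: p.accession_a for p in pairs},
        "accession_b": {p.pair_id: p.accession_b for p in pairs},
        "pair_type": {p.pair_id: p.pair_type for p in pairs},
        "group_id": {p.pair_id: p.group_id for p in pairs},
        "ancestry_class": {p.pair_id: p.ancestry_class for p in pairs},
        "mean_identity": {p.pair_id: p.mean_identity for p in pairs},
    })
    res = meta.loc[res.index].join(res)
    res = classify_pairs(res, fdr=fdr, min_abs_lfc=min_abs_lfc, min_mif=min_mif)
    res.index.name = "pair_id"
    return res


def single_protein_de(glog_quant: pd.DataFrame, design: DesignSpec,
                      fdr: float = 0.01, min_abs_lfc: float = 0.5,
                      complete_case: bool = True) -> pd.DataFrame:
    """Moderated differential expression of individual proteins.

    The same moderated pipeline applied to the glog abundance matrix
    itself; ``de`` flags proteins at the stated thresholds.  This is the
    comparator for the ratio test: pairs can shift significantly while
    neither member passes single-protein DE, and vice versa.
    """
    Y = glog_quant.dropna(axis=0) if complete_case else glog_quant
    fit = ebayes(fit_linear_model(Y, design))
    res = moderated_t(fit)
    res["adj_p"] = bh_adjust(res["p"])
    res["de"] = (res["adj_p"] < fdr) & (res["logFC"].abs() >= min_abs_lfc)
    res.index.name = "accession"
    return res


def cross_tabulate_pair_de(pair_results: pd.DataFrame,
                           protein_results: pd.DataFrame) -> pd.DataFrame:
    """Per significant pair, how many members are individually DE (0/1/2)."""
    sig = pair_results[pair_results["significant"]].copy()
    de = protein_results["de"]

    def n_de(row) -> int:
        return int(de.get(row["accession_a"], False)) + \
            int(de.get(row["accession_b"], False))

    sig["n_members_de"] = sig.apply(n_de, axis=1) if len(sig) else []
    return sig
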