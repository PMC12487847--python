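"""Interpretation layer: proportion profiles, disease-reversal screens,
evolutionary-conservation enrichment, and PCA QC.

Proportion profiles express each isoform group as the fraction of protein
molecules contributed by each member per sample, the natural scale for
statements like "a 60:40 to 40:60 shift".  The reversal screen asks which
developmentally shifted pairs move in the same direction in a disease
contrast, quantifying partial reversion toward the fetal program.
Conservation enrichment relates differential usage to the evolutionary age
of the gene family with Fisher's exact tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .pairing import IsoformGroup

__all__ = [
    "ProportionProfile",
    "ReversalRecord",
    "EnrichmentResult",
    "group_proportions",
    "proportion_fold_change",
    "reversal_analysis",
    "fisher_exact_2x2",
    "conservation_enrichment",
    "identity_vs_de_test",
    "pca_scores",
]

logger = logging.getLogger(__name__)

# Relative tolerance used to include probability ties when summing the
# two-sided exact-test tail (the convention shared by the common exact-test
# implementations, which guards against floating-point near-ties).
_FISHER_TIE_EPS = 1e-7


@dataclass
class ProportionProfile:
    """Per-sample member proportions of one isoform group."""

    group_id: str
    members: list[str]
    proportions: pd.DataFrame        # members × samples, columns sum to 1
    condition_means: pd.DataFrame    # members × conditions
    sem_cumulative: pd.DataFrame     # members × conditions (stacked-sum SEM)
    sem_member: pd.DataFrame         # members × conditions (per-member SEM)
    skipped_samples: list[str]


@dataclass
class ReversalRecord:
    """Co-directionality of one pair between development and disease."""

    pair_id: str
    fetal_logfc: float
    fetal_adj_p: float
    disease_logfc: float
    disease_adj_p: float
    codirectional: bool
    amplitude_ratio: float  # disease |logFC| / fetal |logFC|


@dataclass
class EnrichmentResult:
    """A 2×2 Fisher test of differential usage against a binary category."""

    category: str
    table: np.ndarray  # [[DE & cat, DE & not], [notDE & cat, notDE & not]]
    odds_ratio: float
    p_value: float


def group_proportions(raw_quant: pd.DataFrame, group: IsoformGroup,
                      design: pd.DataFrame,
                      condition_col: str = "condition") -> ProportionProfile:
    """Fraction of the group's protein molecules carried by each member.

    Per sample, member abundance divided by the group total over members
    quantified in that sample (renormalization over present members, with
    the sample flagged when incomplete).  Condition means and the SEM of
    cumulative (stacked) proportions are computed across the biological
    replicates of each condition.
    """
    members = sorted(group.members)
    sub = raw_quant.reindex(members)
    props = {}
    skipped = []
    for sample in raw_quant.columns:
        col = sub[sample]
        present = col.dropna()
        if len(present) < 2 or present.sum() <= 0:
            skipped.append(sample)
            continue
        props[sample] = col / present.sum()
    if not props:
        raise ValueError(f"group {group.group_id}: no sample with >=2 "
                         "quantified members")
    prop = pd.DataFrame(props)
    if skipped:
        warnings.warn(f"group {group.group_id}: samples skipped "
                      f"(insufficient members or zero total): {skipped}")

    cond_of = dict(zip(design["sample"], design[condition_col]))
    conditions = list(dict.fromkeys(design[condition_col]))
    means, sem_cum, sem_mem = {}, {}, {}
    for cond in conditions:
        cols = [s for s in prop.columns if cond_of.get(s) == cond]
        if not cols:
            continue
        block = prop[cols]
        means[cond] = block.mean(axis=1)
        cum = block.fillna(0.0).cumsum(axis=0)
        n = block.shape[1]
        sem_cum[cond] = cum.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else \
            pd.Series(np.nan, index=prop.index)
        sem_mem[cond] = block.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else \
            pd.Series(np.nan, index=prop.index)
    return ProportionProfile(
        group_id=group.group_id,
        members=members,
        proportions=prop,
        condition_means=pd.DataFrame(means),
        sem_cumulative=pd.DataFrame(sem_cum),
        sem_member=pd.DataFrame(sem_mem),
        skipped_samples=skipped,
    )


def proportion_fold_change(p_before: tuple[float, float],
                           p_after: tuple[float, float]) -> float:
    """Fold change of relative abundance implied by a proportion shift.

    For proportions (a1, b1) → (a2, b2) the pair's relative abundance
    changes by (a1/b1) / (a2/b2); the value is reported ≥ 1 (orientation
    fixed), e.g. a 60:40 → 40:60 swap gives (60/40)/(40/60) = 2.25.
    Zero proportions give an infinite fold change with a warning.
    """
    a1, b1 = p_before
    a2, b2 = p_after
    for v in (a1, b1, a2, b2):
        if not (0.0 <= v <= 1.0 or 0.0 <= v <= 100.0):
            raise ValueError("proportions must be fractions or percentages")
    if min(a1, b1, a2, b2) == 0:
        warnings.warn("zero proportion: fold change is infinite")
        return float("inf")
    fc = (a1 / b1) / (a2 / b2)
    return fc if fc >= 1 else 1.0 / fc


def reversal_analysis(fetal_results: pd.DataFrame,
                      disease_results: pd.DataFrame,
                      disease_fdr: float = 0.1,
                      fetal_fdr: float = 0.01,
                      fetal_min_abs_lfc: float = 0.5) -> list[ReversalRecord]:
    """Screen for disease shifts co-directional with the developmental shift.

    Retains pairs that are significant in the fetal/postnatal contrast (at
    the strict 1% FDR and |logFC| ≥ 0.5 by default), reach the looser
    disease FDR (10% by default, regardless of fold-change magnitude), and
    move in the same direction in both contrasts.  The amplitude ratio
    disease |logFC| / fetal |logFC| measures how partial the reversal is.
    Output order is deterministic (sorted by pair id) regardless of the
    input row order.
    """
    shared = fetal_results.index.intersection(disease_results.index)
    if shared.empty:
        warnings.warn("fetal and disease result sets share no pair ids")
        return []
    records = []
    for pid in sorted(shared):
        f = fetal_results.loc[pid]
        d = disease_results.loc[pid]
        fetal_sig = bool(f.get("significant",
                                (f["adj_p"] < fetal_fdr)
                                and abs(f["logFC"]) >= fetal_min_abs_lfc))
        if not fetal_sig:
            continue
        if not (np.isfinite(d["adj_p"]) and d["adj_p"] <= disease_fdr):
            continue
        codir = np.sign(f["logFC"]) == np.sign(d["logFC"]) and d["logFC"] != 0
        if not codir:
            continue
        records.append(ReversalRecord(
            pair_id=pid,
            fetal_logfc=float(f["logFC"]),
            fetal_adj_p=float(f["adj_p"]),
            disease_logfc=float(d["logFC"]),
            disease_adj_p=float(d["adj_p"]),
            codirectional=True,
            amplitude_ratio=abs(d["logFC"]) / abs(f["logFC"]),
        ))
    return records


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 table: (sample odds ratio, two-sided p).

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of the
    observed table (probability-mass ordering, with a small relative
    tolerance for floating-point ties).  The odds ratio is the sample
    (cross-product) estimate ad/bc; NaN when a margin is zero (p = 1).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValueError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, c1, n - r1, n - c1) == 0 or n == 0:
        warnings.warn("zero margin: odds ratio undefined, p = 1")
        return float("nan"), 1.0
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_TIE_EPS)].sum())
    return odds, min(p, 1.0)


def conservation_enrichment(pairs: pd.DataFrame,
                            de_flags: pd.Series | Mapping[str, bool],
                            schemes: Mapping[str, Mapping[str, bool]] | None = None,
                            ) -> list[EnrichmentResult]:
    """Fisher tests of differential usage against evolutionary-age categories.

    ``pairs`` must carry ``ancestry_class`` (and optionally other columns
    used by custom schemes); ``de_flags`` maps pair id → bool.  By default
    one test is run for the ancient/recent family-origin classification;
    additional binary schemes (e.g. Ensembl paralog type, opisthokonta
    membership) may be supplied as pair-id → bool mappings.  Categories
    with an empty cellrow are skipped with a warning.
    """
    de = pd.Series(de_flags).astype(bool)
    results: list[EnrichmentResult] = []

    default: dict[str, pd.Series] = {}
    if "ancestry_class" in pairs.columns:
        cls = pairs["ancestry_class"]
        known = cls.isin(["ancient", "recent"])
        default["ancient_family"] = (cls == "ancient")[known]
    all_schemes: dict[str, pd.Series] = dict(default)
    if schemes:
        for name, mapping in schemes.items():
            all_schemes[name] = pd.Series(mapping).astype(bool)

    for name, in_cat in all_schemes.items():
        idx = in_cat.index.intersection(de.index)
        if idx.empty:
            warnings.warn(f"scheme {name!r}: no overlapping pairs; skipped")
            continue
        cat = in_cat.loc[idx]
        flag = de.loc[idx]
        if cat.nunique() < 2:
            warnings.warn(f"scheme {name!r}: single category present; skipped")
            continue
        tab = np.array([
            [int((flag & cat).sum()), int((flag & ~cat).sum())],
            [int((~flag & cat).sum()), int((~flag & ~cat).sum())],
        ])
        odds, p = fisher_exact_2x2(tab)
        results.append(EnrichmentResult(category=name, table=tab,
                                        odds_ratio=odds, p_value=p))
    return results


def identity_vs_de_test(mean_identities: pd.Series,
                        de_flags: pd.Series,
                        equal_var: bool = False) -> tuple[float, float]:
    """Two-sided t-test of mean sequence identity by differential-usage status.

    Welch's test by default (``equal_var=True`` gives the pooled-variance
    version).  Returns (t, p).  Requires ≥2 observations in each class.
    """
    idx = mean_identities.index.intersection(de_flags.index)
    ident = mean_identities.loc[idx].astype(float)
    flag = de_flags.loc[idx].astype(bool)
    ok = ident.notna()
    x = ident[ok & flag]
    y = ident[ok & ~flag]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 identity values per class "
                         f"(got {len(x)} DE, {len(y)} non-DE)")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2,
               scale: bool = False) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Principal-component scores of samples from a feature × sample matrix.

    Rows with any missing value are dropped (their count is returned);
    samples are the observations.  Values are centered per feature
    (optionally unit-scaled); explained variance ratios are non-increasing.
    Returns (scores samples × components, explained variance ratio,
    n complete rows used).
    """
    complete = matrix.dropna(axis=0)
    n_used = len(complete)
    if n_used < n_components:
        raise ValueError(f"only {n_used} complete rows for "
                         f"{n_components} components")
    X = complete.to_numpy(dtype=float).T  # samples × features
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.columns, columns=cols),
            pca.explained_variance_ratio_, n_used)
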