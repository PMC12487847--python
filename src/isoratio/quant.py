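"""Absolute protein quantification from composite MS1–MS2 TMT data.

The estimator follows the iBAQ idea adapted to isobaric multiplexing: each
PSM's MS1 precursor intensity is apportioned across TMT channels in
proportion to the MS2 reporter-ion intensities, apportioned intensities are
summed per protein over that protein's *unique* PSMs, and the sum is divided
by the number of theoretically observable tryptic peptides.  The result is a
per-channel absolute abundance estimate on a common (arbitrary) scale, which
makes ratios between different proteins meaningful within a sample.

Variance stabilization uses a generalized-log (glog) transform after
per-sample median scaling; see :func:`glog_normalize`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .io import reporter_columns

__all__ = [
    "PsmRecord",
    "GlogParameters",
    "DigestionParams",
    "tryptic_peptide_count",
    "apportion_channels",
    "protein_absolute_quant",
    "glog_transform",
    "glog_normalize",
    "qc_correlation",
    "UnquantifiablePsmError",
]

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class UnquantifiablePsmError(ValueError):
    """Raised when a PSM has an all-zero reporter vector (no channel signal)."""


@dataclass
class PsmRecord:
    """One identified spectrum: the atomic quantification input."""

    peptide_sequence: str
    protein_accessions: list[str]
    ms1_intensity: float
    reporter_intensities: np.ndarray
    source_run: str = ""

    def __post_init__(self) -> None:
        self.reporter_intensities = np.asarray(self.reporter_intensities, dtype=float)
        if self.ms1_intensity < 0:
            raise ValueError("ms1_intensity must be non-negative")
        if (self.reporter_intensities < 0).any():
            raise ValueError("reporter intensities must be non-negative")


@dataclass
class GlogParameters:
    """Per-sample normalization constants of the glog transform.

    ``scale`` is the multiplicative median-scaling factor applied to each
    sample; ``offset_c`` is the sample's glog soft-zero constant ``c`` in
    ``glog2(v) = log2((v + sqrt(v^2 + c^2)) / 2)``.
    """

    offset_c: pd.Series
    scale: pd.Series


@dataclass(frozen=True)
class DigestionParams:
    """In-silico digestion constants for theoretical peptide counting.

    Fully tryptic cleavage (C-terminal to K/R, suppressed before proline),
    zero missed cleavages, and a peptide length window of 7–30 residues —
    the usual observable range for shotgun proteomics.
    """

    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0


def tryptic_peptide_count(protein_sequence: str, min_len: int = 7,
                          max_len: int = 30, missed_cleavages: int = 0) -> int:
    """Number of fully tryptic peptides of a protein within a length window.

    Cleaves C-terminal to K/R except before P (no missed cleavages by
    default) and counts fragments with length in ``[min_len, max_len]``.
    This is the denominator of the iBAQ-style abundance estimate.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    seq = protein_sequence.upper()
    illegal = set(seq) - _AA_ALPHABET
    if illegal:
        raise ValueError(f"illegal amino-acid characters: {sorted(illegal)}")
    n = 0
    for _, pep in _pyt_parser.icleave(seq, _pyt_parser.expasy_rules["trypsin"],
                                      missed_cleavages=missed_cleavages):
        if min_len <= len(pep) <= max_len:
            n += 1
    return n


def apportion_channels(ms1_intensity: float,
                       reporter_intensities: Sequence[float]) -> np.ndarray:
    """Distribute one PSM's MS1 precursor intensity across TMT channels.

    Channel *i* receives ``ms1_intensity * reporter_i / sum(reporters)``, so
    the output sums exactly to the MS1 intensity.  An all-zero reporter
    vector carries no channel information and raises
    :class:`UnquantifiablePsmError` rather than returning zeros.
    """
    rep = np.asarray(reporter_intensities, dtype=float)
    if ms1_intensity < 0 or (rep < 0).any():
        raise ValueError("intensities must be non-negative")
    total = rep.sum()
    if total <= 0:
        raise UnquantifiablePsmError("all-zero reporter vector: PSM unquantifiable")
    # fractions first: rep/total is well-scaled in [0, 1], which keeps the
    # split exact even for subnormal reporter intensities
    return ms1_intensity * (rep / total)


def _psms_to_frame(psms: Sequence[PsmRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(psms, pd.DataFrame):
        return psms
    n_chan = len(psms[0].reporter_intensities)
    rows = {
        "peptide": [p.peptide_sequence for p in psms],
        "proteins": [";".join(p.protein_accessions) for p in psms],
        "ms1_intensity": [p.ms1_intensity for p in psms],
    }
    rep = np.vstack([p.reporter_intensities for p in psms])
    for i in range(n_chan):
        rows[f"reporter_{i + 1}"] = rep[:, i]
    return pd.DataFrame(rows)


def protein_absolute_quant(
    psms: Sequence[PsmRecord] | pd.DataFrame,
    fasta_map: Mapping[str, str],
    design: pd.DataFrame,
    digestion: DigestionParams = DigestionParams(),
    razor: str = "exclude",
) -> pd.DataFrame:
    """Aggregate PSMs into a proteins × samples absolute-abundance matrix.

    Only PSMs whose peptide maps to exactly one accession contribute
    (shared peptides cannot be attributed between ~90%-identical isoforms;
    the default razor rule excludes them everywhere).  Per accession and
    channel, apportioned intensities are summed over unique PSMs and divided
    by the accession's theoretical tryptic peptide count.  Proteins with no
    unique quantifiable PSM are absent from the output (missing, not zero).

    Parameters
    ----------
    psms
        PSM table (DataFrame dialect of :func:`isoratio.io.read_psm_table`)
        or a list of :class:`PsmRecord`.
    fasta_map
        accession → protein sequence; every quantified accession must be
        present.
    design
        sample design table with ``sample`` and ``channel`` columns; the
        reporter columns ``reporter_<channel>`` of the PSM table are mapped
        onto sample names through it.
    razor
        ``"exclude"`` (default) drops shared-peptide PSMs entirely.
    """
    if razor != "exclude":
        raise NotImplementedError("only the 'exclude' razor rule is implemented")
    df = _psms_to_frame(psms)
    rep_cols = reporter_columns(df.columns)
    channels = [c.removeprefix("reporter_") for c in rep_cols]
    design_channels = design["channel"].astype(str).tolist()
    if set(channels) != set(design_channels):
        raise ValueError(
            f"PSM reporter channels {channels} do not match design channels "
            f"{design_channels}")
    chan_to_sample = dict(zip(design["channel"].astype(str), design["sample"]))
    samples = [chan_to_sample[c] for c in channels]

    rep = df[rep_cols].to_numpy(dtype=float)
    ms1 = df["ms1_intensity"].to_numpy(dtype=float)
    rep_total = rep.sum(axis=1)

    unquantifiable = rep_total <= 0
    n_unq = int(unquantifiable.sum())
    if n_unq:
        logger.info("excluding %d unquantifiable PSMs (all-zero reporters)", n_unq)

    shared = df["proteins"].str.contains(";").to_numpy()
    n_shared = int(shared.sum())
    if n_shared:
        logger.info("excluding %d shared-peptide PSMs (razor rule: exclude)", n_shared)

    keep = ~unquantifiable & ~shared
    if not keep.any():
        raise ValueError("no quantifiable unique PSMs in input")

    with np.errstate(invalid="ignore", divide="ignore"):
        apportioned = ms1[keep, None] * (rep[keep] / rep_total[keep, None])
    acc = df.loc[keep, "proteins"].to_numpy()

    missing_acc = sorted(set(acc) - set(fasta_map))
    if missing_acc:
        raise KeyError(f"accessions absent from FASTA: {missing_acc}")

    sums = pd.DataFrame(apportioned, columns=samples).groupby(acc).sum()
    counts = pd.Series(
        {a: tryptic_peptide_count(fasta_map[a], digestion.min_len,
                                  digestion.max_len, digestion.missed_cleavages)
         for a in sums.index},
        dtype=float,
    )
    zero_pep = counts[counts == 0].index.tolist()
    if zero_pep:
        logger.warning("dropping %d proteins with no theoretical peptides: %s",
                       len(zero_pep), zero_pep[:5])
        sums = sums.drop(index=zero_pep)
        counts = counts.drop(index=zero_pep)
    matrix = sums.div(counts, axis=0)
    # keep design order of samples
    ordered = [chan_to_sample[c] for c in design_channels]
    return matrix[ordered]


def glog_transform(values: np.ndarray | pd.DataFrame, c: float | np.ndarray):
    """Generalized log2: ``log2((v + sqrt(v^2 + c^2)) / 2)``.

    Finite at v = 0 (where it equals ``log2(c/2)``), strictly monotone in v,
    and asymptotically equal to ``log2(v)`` for ``v >> c``.
    """
    v = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) else values
    out = np.log2((v + np.sqrt(v ** 2 + np.square(c))) / 2.0)
    return out


def glog_normalize(
    matrix: pd.DataFrame,
    c_quantile: float = 0.05,
) -> tuple[pd.DataFrame, GlogParameters]:
    """Variance-stabilize a protein quantification matrix.

    Two steps, both per sample: (1) multiplicative median scaling so that
    the median abundance of proteins quantified in every sample agrees
    across samples; (2) a glog2 transform whose soft-zero constant ``c`` is
    the ``c_quantile`` quantile (default 5th percentile) of that sample's
    positive scaled intensities.  This preserves the variance-stabilizing
    intent of VSN-style calibration with a transparent closed form.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    all_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"sample(s) with no quantified proteins: {list(all_missing)}")
    per_sample_n = matrix.notna().sum(axis=0)
    if (per_sample_n < 10).any():
        low = per_sample_n[per_sample_n < 10].index.tolist()
        raise ValueError(f"fewer than 10 quantified proteins in sample(s): {low}")

    complete = matrix.dropna(axis=0)
    if complete.empty:
        warnings.warn("no proteins quantified in all samples; "
                      "median scaling uses per-sample medians instead")
        sample_medians = matrix.median(axis=0)
    else:
        sample_medians = complete.median(axis=0)
    target = np.exp(np.log(sample_medians).mean())  # geometric mean of medians
    scale = target / sample_medians
    scaled = matrix * scale

    c = scaled[scaled > 0].quantile(c_quantile, axis=0)
    transformed = np.log2((scaled + np.sqrt(scaled ** 2 + c ** 2)) / 2.0)
    return transformed, GlogParameters(offset_c=c, scale=scale)


def qc_correlation(matrix: pd.DataFrame, log_scale: bool = True,
                   min_overlap: int = 3) -> pd.DataFrame:
    """Sample × sample Pearson correlation of shared quantified proteins.

    With ``log_scale`` the correlation is computed on log10 intensities
    (zeros excluded), which is the conventional scale for abundance QC
    scatter.  Sample pairs sharing fewer than ``min_overlap`` proteins get a
    missing cell and a warning.
    """
    m = matrix.copy()
    if log_scale:
        m = m.where(m > 0)
        m = np.log10(m)
    cols = list(m.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = m[[a, b]].dropna()
            if len(pair) < min_overlap:
                warnings.warn(f"samples {a}/{b} share only {len(pair)} proteins; "
                              "correlation not computed")
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            r = np.corrcoef(pair[a], pair[b])[0, 1]
            out.loc[a, b] = out.loc[b, a] = r
    return out
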