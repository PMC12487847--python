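"""High-level composition of the workflow stages.

The canonical chain is: PSM table → absolute quantification → glog
normalization → isoform pairing (paralogs from homology, spliceoforms from
accessions) → moderated ratio test → downstream summaries.  Each stage is
an importable function; the command-line interface is a thin wrapper over
these.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairing import IsoformPair, build_paralog_pairs, build_spliceoform_pairs
from .quant import DigestionParams, glog_normalize, protein_absolute_quant
from .ratiotest import build_design, ratio_test
from .simulate import (SyntheticConfig, SyntheticDataset, apply_missingness,
                       recovery_report, simulate_dataset)

__all__ = [
    "Thresholds",
    "quantify",
    "pair",
    "test_ratios",
    "run_benchmark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds of the workflow (all overridable).

    Defaults: 1% BH FDR with |logFC| ≥ 0.5 and MIF ≥ 0.05 for the primary
    contrast (the stricter-than-usual FDR partially accounts for the
    nonindependence of ratios sharing a protein), ≥50% mean sequence
    identity for paralog pairing, and 10% FDR for disease co-directionality
    screens.
    """

    fdr: float = 0.01
    min_abs_lfc: float = 0.5
    min_mif: float = 0.05
    min_identity: float = 50.0
    disease_fdr: float = 0.1


def quantify(psm_table: pd.DataFrame, fasta_map: Mapping[str, str],
             design: pd.DataFrame,
             digestion: DigestionParams = DigestionParams(),
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSMs → (raw absolute-abundance matrix, glog-normalized matrix)."""
    raw = protein_absolute_quant(psm_table, fasta_map, design, digestion)
    glog, _ = glog_normalize(raw)
    return raw, glog


def pair(raw: pd.DataFrame, homology: pd.DataFrame | None,
         gene_map: Mapping[str, str],
         min_identity: float = 50.0,
         include_spliceoforms: bool = True) -> list[IsoformPair]:
    """Quantified accessions → paralog + spliceoform pair list."""
    pairs: list[IsoformPair] = []
    if homology is not None and len(homology):
        paralog_pairs, _ = build_paralog_pairs(
            homology, raw.index, gene_map, min_identity=min_identity)
        pairs.extend(paralog_pairs)
    if include_spliceoforms:
        covered = {p.pair_id for p in pairs}
        for sp in build_spliceoform_pairs(raw.index):
            if sp.pair_id not in covered:
                pairs.append(sp)
    return pairs


def test_ratios(glog: pd.DataFrame, raw: pd.DataFrame,
                pairs: Sequence[IsoformPair], design_table: pd.DataFrame,
                formula: str = "~ condition", contrast: str | None = None,
                thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Moderated ratio test of every pair under a design formula."""
    design = build_design(design_table, formula=formula, contrast=contrast)
    return ratio_test(glog, raw, pairs, design,
                      fdr=thresholds.fdr,
                      min_abs_lfc=thresholds.min_abs_lfc,
                      min_mif=thresholds.min_mif)


def run_benchmark(config: SyntheticConfig,
                  thresholds: Thresholds = Thresholds(),
                  ) -> tuple[pd.DataFrame, dict[str, float], SyntheticDataset]:
    """Simulate → quantify → pair → test → score, end to end.

    Returns the ratio-test result table, the parameter-recovery report and
    the simulated dataset itself.  Missingness (if configured) is applied
    at the protein × sample level after quantification, before
    normalization, using a generator derived from the config seed.
    """
    data = simulate_dataset(config)
    raw = protein_absolute_quant(data.psm_table, data.fasta, data.design)
    if config.missing_rate > 0:
        rng = np.random.default_rng(config.seed + 1)
        raw = apply_missingness(raw, config.missing_rate, rng)
    glog, _ = glog_normalize(raw)
    pairs = pair(raw, data.homology, data.gene_map,
                 min_identity=thresholds.min_identity)
    results = test_ratios(glog, raw, pairs, data.design,
                          formula="~ condition", thresholds=thresholds)
    report = recovery_report(results, data.truth)
    return results, report, data
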