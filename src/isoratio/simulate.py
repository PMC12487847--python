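"""Synthetic PSM-level TMT experiments with known ground truth.

The generator emulates the statistical features of an MS2-multiplexed
proteomics run that matter for ratio testing:

* protein copy numbers spanning several orders of magnitude (log-uniform);
* isoform groups whose members split a shared protein pool according to
  per-condition proportions, so a "shift" is a change in log2 odds of the
  member proportions between conditions;
* synthetic tryptic-digestible sequences whose theoretical peptide count
  matches the peptides actually emitted (so iBAQ-style division recovers
  copy numbers), with KP motifs injected to exercise cleavage suppression;
* peptide-level multiplicative lognormal noise on both the MS1 precursor
  intensity and the per-channel reporter intensities;
* reporter-ion co-isolation interference: a configurable fraction of the
  channel-mean background is mixed into every PSM's reporters, which
  compresses measured ratios toward 1:1 exactly as co-eluting isobaric
  peptides do;
* missing-at-random dropout at the protein × sample level (applied after
  quantification, matching the complete-case filter's assumptions).

It does not simulate chromatography, isotope envelopes, spectra, or
search-engine errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "apply_missingness",
    "recovery_report",
    "BENCHMARK_CONFIG",
]

# Residues used inside synthetic peptides: no K/R (cleavage sites are
# placed explicitly at peptide ends) and no P (so every junction cleaves).
_PEPTIDE_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))

_ANCIENT_TAXA_POOL = ["Opisthokonta", "Bilateria"]
_RECENT_TAXA_POOL = ["Vertebrata", "Mammalia", "Euarchontoglires", "Muroidea"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic TMT experiment.

    The defaults are the standard benchmark: 1500 background proteins and
    200 two-member paralog groups (100 null, 100 carrying a glog2 ratio
    shift of 1.0 between conditions), one 10-plex with 5 samples per
    condition, 20% peptide-level CV, no interference, no missingness.
    """

    n_background: int = 1500
    n_groups: int = 200
    group_size: int = 2
    n_shifted: int = 100
    shift_glog2: float = 1.0
    n_spliceoform_groups: int = 0
    plex_size: int = 10
    n_per_condition: int = 5
    conditions: tuple[str, str] = ("fetal", "postnatal")
    copy_number_orders: float = 5.0
    copy_number_min: float = 1e2
    peptide_cv: float = 0.2
    interference: float = 0.0
    missing_rate: float = 0.0
    peptides_mean: float = 10.0
    kp_motif_rate: float = 0.1
    min_proportion: float = 0.25
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_shifted > self.n_groups:
            raise ValueError("n_shifted cannot exceed n_groups")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if not (0.0 <= self.interference < 1.0):
            raise ValueError("interference must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.plex_size < 2 * self.n_per_condition:
            raise ValueError("plex smaller than the number of samples")


@dataclass
class SyntheticGroundTruth:
    """The simulator's true state, for parameter-recovery scoring."""

    copy_numbers: pd.DataFrame          # proteins × samples true abundance
    proportions: dict[str, pd.DataFrame]  # group -> members × conditions
    pair_truth: pd.DataFrame            # pair_id → true_logfc, is_shifted
    config: SyntheticConfig


@dataclass
class SyntheticDataset:
    """All artifacts of one simulated experiment, in-memory."""

    psm_table: pd.DataFrame
    fasta: dict[str, str]
    gene_map: dict[str, str]
    homology: pd.DataFrame
    design: pd.DataFrame
    truth: SyntheticGroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five standard-dialect files; returns their paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "psm": out / "psms.tsv",
            "fasta": out / "proteins.fasta",
            "homology": out / "homology.tsv",
            "design": out / "design.csv",
            "truth": out / "ground_truth.tsv",
        }
        _io.write_psm_table(self.psm_table, paths["psm"])
        _io.write_fasta(self.fasta, paths["fasta"], genes=self.gene_map)
        _io.write_homology_table(self.homology, paths["homology"])
        _io.write_design_table(self.design, paths["design"])
        self.truth.pair_truth.to_csv(paths["truth"], sep="\t", na_rep="NA")
        return paths


def _make_peptides(rng: np.random.Generator, n: int, kp_rate: float,
                   used: set[str]) -> list[str]:
    """n unique tryptic peptides (length 7–30 incl. terminal K/R)."""
    peptides: list[str] = []
    while len(peptides) < n:
        length = int(rng.integers(7, 31))
        body = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length - 1))
        if length <= 28 and rng.random() < kp_rate:
            # internal KP motif: K followed by P does not cleave
            pos = int(rng.integers(1, len(body)))
            body = body[:pos] + "KP" + body[pos:]
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep in used:
            continue
        used.add(pep)
        peptides.append(pep)
    return peptides


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _logit2(p: np.ndarray) -> np.ndarray:
    return np.log2(p / (1.0 - p))


def _inv_logit2(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-x))


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic TMT experiment.

    Deterministic for a fixed config (including seed).  Copy numbers are
    drawn log-uniformly so that the inner 99% of the distribution spans the
    configured number of orders of magnitude.  For two-member groups the
    true pair logFC (glog2(a) − glog2(b), second condition minus first) is
    ``±shift_glog2`` with random sign for shifted groups and 0 for null
    groups; for larger groups the shift is applied to the first member's
    log2 odds against the rest.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_samples = 2 * cfg.n_per_condition
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    condition = ([cfg.conditions[0]] * cfg.n_per_condition
                 + [cfg.conditions[1]] * cfg.n_per_condition)
    channels = [f"{126 + i}" for i in range(cfg.plex_size)]
    design = pd.DataFrame({
        "sample": samples,
        "channel": channels[:n_samples],
        "condition": condition,
    })

    # --- accessions, genes, group membership -------------------------------
    accs: list[str] = [f"B{i + 1:05d}" for i in range(cfg.n_background)]
    gene_map: dict[str, str] = {a: f"g{a}" for a in accs}
    groups: list[list[str]] = []
    group_ids: list[str] = []
    member_letters = "ABCDEFGH"
    for g in range(cfg.n_groups):
        gid = f"PG{g + 1:04d}"
        members = [f"{gid}{member_letters[k]}" for k in range(cfg.group_size)]
        groups.append(members)
        group_ids.append(gid)
        for m in members:
            gene_map[m] = f"g{m}"
        accs.extend(members)
    for s in range(cfg.n_spliceoform_groups):
        gid = f"SP{s + 1:04d}"
        base = f"{gid}Q"
        members = [base, f"{base}-2"]
        groups.append(members)
        group_ids.append(gid)
        for m in members:
            gene_map[m] = f"g{base}"
        accs.extend(members)

    n_groups_total = len(groups)
    shifted = np.zeros(n_groups_total, dtype=bool)
    shifted[:cfg.n_shifted] = True  # first n_shifted paralog groups shift
    shift_signs = rng.choice([-1.0, 1.0], size=n_groups_total)

    # --- true abundances ----------------------------------------------------
    span = cfg.copy_number_orders / 0.98  # inner-99% coverage with margin
    lo = np.log10(cfg.copy_number_min)

    bg_copy = 10 ** rng.uniform(lo, lo + span, size=cfg.n_background)
    truth_rows: dict[str, np.ndarray] = {
        a: np.full(n_samples, c) for a, c in zip(accs[:cfg.n_background], bg_copy)
    }

    proportions: dict[str, pd.DataFrame] = {}
    pair_rows = []
    group_totals = 10 ** rng.uniform(lo, lo + span, size=n_groups_total)
    cond_idx = np.array([0] * cfg.n_per_condition + [1] * cfg.n_per_condition)
    for gi, (gid, members) in enumerate(zip(group_ids, groups)):
        k = len(members)
        base = rng.dirichlet(np.full(k, 5.0))
        floor = cfg.min_proportion / k
        base = (base + floor) / (1.0 + k * floor)  # keep minor members visible
        props = np.tile(base, (2, 1))  # conditions × members
        delta = cfg.shift_glog2 * shift_signs[gi] if shifted[gi] else 0.0
        if delta != 0.0:
            # shift member 0's log2 odds against the rest in condition 2
            p0 = props[1, 0]
            p0_new = float(_inv_logit2(_logit2(np.array([p0])) + delta)[0])
            props[1, 0] = p0_new
            props[1, 1:] *= (1.0 - p0_new) / (1.0 - p0)
        prop_df = pd.DataFrame(props.T, index=members, columns=list(cfg.conditions))
        proportions[gid] = prop_df
        total = group_totals[gi]
        for mi, m in enumerate(members):
            truth_rows[m] = props[cond_idx, mi] * total
        # true logFC for every within-group pair, canonical orientation
        for i in range(k):
            for j in range(i + 1, k):
                a, b = sorted((members[i], members[j]))
                lfc = (np.log2(prop_df.loc[a, cfg.conditions[1]]
                               / prop_df.loc[b, cfg.conditions[1]])
                       - np.log2(prop_df.loc[a, cfg.conditions[0]]
                                 / prop_df.loc[b, cfg.conditions[0]]))
                pair_rows.append({
                    "pair_id": f"{a}|{b}",
                    "group_id": gid,
                    "true_logfc": lfc,
                    "is_shifted": bool(shifted[gi]),
                })
    copy_numbers = pd.DataFrame(truth_rows, index=samples).T
    copy_numbers = copy_numbers.loc[accs]
    pair_truth = pd.DataFrame(pair_rows).set_index("pair_id")

    # --- sequences ----------------------------------------------------------
    n_peptides = 1 + rng.poisson(max(cfg.peptides_mean - 1.0, 0.0), size=len(accs))
    used: set[str] = set()
    fasta: dict[str, str] = {}
    peptide_lists: list[list[str]] = []
    for acc, npep in zip(accs, n_peptides):
        peps = _make_peptides(rng, int(npep), cfg.kp_motif_rate, used)
        peptide_lists.append(peps)
        fasta[acc] = "".join(peps)

    # --- PSM-level intensities ----------------------------------------------
    abundance = copy_numbers.to_numpy()          # proteins × samples
    channel_mean = abundance.mean(axis=0)        # co-isolation background
    psm_acc, psm_pep, psm_ms1, psm_rep = [], [], [], []
    for pi, (acc, peps) in enumerate(zip(accs, peptide_lists)):
        a = abundance[pi]
        total = a.sum()
        resp = _lognormal_noise(rng, cfg.peptide_cv, len(peps))
        eps = _lognormal_noise(rng, cfg.peptide_cv, (len(peps), n_samples))
        reporters = (a + cfg.interference * channel_mean) * eps
        for j, pep in enumerate(peps):
            psm_acc.append(acc)
            psm_pep.append(pep)
            psm_ms1.append(total * resp[j])
            psm_rep.append(reporters[j])
    rep_arr = np.vstack(psm_rep)
    psm_table = pd.concat(
        [pd.DataFrame({"peptide": psm_pep, "proteins": psm_acc,
                       "ms1_intensity": psm_ms1}),
         pd.DataFrame(rep_arr, columns=[f"reporter_{ch}"
                                        for ch in channels[:n_samples]])],
        axis=1)
    psm_table["run"] = "sim_run1"

    # --- homology table (paralog groups only) -------------------------------
    hom_rows = []
    for gi, (gid, members) in enumerate(zip(group_ids, groups)):
        if gid.startswith("SP"):
            continue
        ancient = rng.random() < 0.5
        taxon = (rng.choice(_ANCIENT_TAXA_POOL) if ancient
                 else rng.choice(_RECENT_TAXA_POOL))
        ptype = ("other_paralog" if ancient else "within_species_paralog")
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = rng.uniform(55.0, 95.0)
                hom_rows.append({
                    "gene_id": gene_map[members[i]],
                    "paralog_gene_id": gene_map[members[j]],
                    "perc_id": round(ident + rng.uniform(-2, 2), 2),
                    "perc_id_r1": round(ident + rng.uniform(-2, 2), 2),
                    "paralog_type": ptype,
                    "ancestor": taxon,
                })
    homology = pd.DataFrame(
        hom_rows, columns=["gene_id", "paralog_gene_id", "perc_id",
                           "perc_id_r1", "paralog_type", "ancestor"])

    truth = SyntheticGroundTruth(copy_numbers=copy_numbers,
                                 proportions=proportions,
                                 pair_truth=pair_truth, config=cfg)
    return SyntheticDataset(psm_table=psm_table, fasta=fasta,
                            gene_map=gene_map, homology=homology,
                            design=design, truth=truth)


def apply_missingness(matrix: pd.DataFrame, rate: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Missing-at-random dropout at the protein × sample level."""
    if rate <= 0:
        return matrix
    mask = rng.random(matrix.shape) < rate
    out = matrix.copy()
    out[mask] = np.nan
    return out


def recovery_report(estimates: pd.DataFrame,
                    truth: SyntheticGroundTruth) -> dict[str, float]:
    """Score ratio-test results against the simulator's ground truth.

    ``estimates`` is the ratio-test result table (indexed by pair id, with
    ``logFC`` and ``significant`` columns).  Reports logFC bias and RMSE
    over true-shift pairs, sensitivity (shifted pairs declared significant /
    shifted pairs tested), and the observed FDR among declared positives.
    Sensitivity and bias are NaN when the truth contains no shifted pairs.
    """
    tt = truth.pair_truth
    shared = estimates.index.intersection(tt.index)
    if shared.empty:
        raise ValueError("estimates and ground truth share no pair ids")
    est = estimates.loc[shared]
    tru = tt.loc[shared]

    shifted = tru["is_shifted"].astype(bool)
    declared = est["significant"].astype(bool)

    report: dict[str, float] = {
        "n_pairs_tested": float(len(shared)),
        "n_true_shifted": float(shifted.sum()),
        "n_declared": float(declared.sum()),
    }
    if shifted.any():
        err = est.loc[shifted, "logFC"] - tru.loc[shifted, "true_logfc"]
        report["logfc_bias"] = float(err.mean())
        report["logfc_rmse"] = float(np.sqrt((err ** 2).mean()))
        report["sensitivity"] = float((declared & shifted).sum() / shifted.sum())
    else:
        report["logfc_bias"] = float("nan")
        report["logfc_rmse"] = float("nan")
        report["sensitivity"] = float("nan")
    if declared.any():
        report["observed_fdr"] = float((declared & ~shifted).sum() / declared.sum())
    else:
        report["observed_fdr"] = 0.0
    return report


#: The standard benchmark condition used throughout the test-bench:
#: 1500 background proteins, 200 two-member groups (100 null, 100 with a
#: glog2 ratio shift of 1.0), 5+5 samples in one 10-plex, peptide CV 0.2,
#: no interference, no missingness, seed 17.
BENCHMARK_CONFIG = SyntheticConfig()
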