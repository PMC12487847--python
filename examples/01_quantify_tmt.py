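"""Absolute protein quantification from a simulated TMT experiment.

Simulates a small PSM-level 10-plex, converts composite MS1–MS2 signals
into per-channel absolute abundances (iBAQ-style), and prints the dynamic
range and between-sample agreement.
"""

from dataclasses import replace

import numpy as np

import isoratio as ir

cfg = replace(ir.BENCHMARK_CONFIG, n_background=300, n_groups=30,
              n_shifted=15, seed=1)
data = ir.simulate_dataset(cfg)
raw = ir.protein_absolute_quant(data.psm_table, data.fasta, data.design)
glog, params = ir.glog_normalize(raw)

lo, hi = np.nanquantile(raw.values, [0.005, 0.995])
print(f"quantified {raw.shape[0]} proteins x {raw.shape[1]} samples "
      f"from {len(data.psm_table)} PSMs")
print(f"abundance span (inner 99%): {np.log10(hi / lo):.1f} orders of magnitude")

corr = ir.qc_correlation(raw, log_scale=True)
within = corr.iloc[:5, :5].values[np.triu_indices(5, 1)]
print(f"median within-condition log-intensity Pearson r: "
      f"{np.median(within):.3f}")
# High r means channels of the same condition measure the same proteome
# consistently; the 5-order span shows low-abundance proteins are retained.
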