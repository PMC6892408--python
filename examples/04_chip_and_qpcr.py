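"""ChIP peak filtering and qPCR double normalisation.

Filters a synthetic peak table to promoter-proximal (TSS +- 1 kb),
adequately covered (>= 4 reads in at least one genotype) peaks and flags
the significantly different ones (>= 2-fold, IDR < 0.05); then normalises
a small qPCR experiment to the reference gene and to the WT group mean.
"""

import numpy as np

import mgmorph as mg

peaks = mg.generate_peak_table(n_peaks=2000, n_true=40, seed=3)
retained, significant = mg.chip_peak_filter(peaks)
print(f"peaks: {len(peaks)} total -> {len(retained)} retained "
      f"-> {len(significant)} significantly different")
recovered = significant["true_diff"].sum()
print(f"of {peaks['true_diff'].sum()} truly differential peaks, "
      f"{recovered} fall in the significant set")

# qPCR: 4 WT and 4 KO samples, KO expressing the gene at half the WT level
rng = np.random.default_rng(4)
groups = ["WT"] * 4 + ["KO"] * 4
ct_ref = rng.normal(20.0, 0.1, size=8)
ct_gene = ct_ref + 5.0 + np.r_[np.zeros(4), np.ones(4)]  # +1 cycle in KO
rel = mg.qpcr_relative_expression(ct_gene, ct_ref, groups)
wt = rel[np.asarray(groups) == "WT"]
ko = rel[np.asarray(groups) == "KO"]
print(f"relative expression: WT mean = {wt.mean():.3f}, KO mean = {ko.mean():.3f}")

# WT normalises to exactly 1 by construction; the extra KO cycle halves
# expression, so the KO mean sits near 0.5.
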