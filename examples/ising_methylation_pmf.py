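"""Methylation-level distribution of one genomic unit (GU).

Builds a 6-CpG GU with a mildly methylated field and positive
nearest-neighbor coupling, computes the exact PMF of the methylation
level M, and prints the two scalar summaries: the mean methylation level
(MML, the expected fraction of methylated CpGs) and the normalized
methylation entropy (NME, 0 = deterministic, 1 = maximally disordered).
"""

import numpy as np

from methrank import IsingGU, level_pmf_from_ising, mml, nme

gu = IsingGU(cpg_count=6, field=np.full(6, 0.8), coupling=np.full(5, 0.4))
pmf = level_pmf_from_ising(gu)

print("level  probability")
for level, prob in zip(pmf.levels, pmf.probs):
    print(f"{level:5.3f}  {prob:.4f}")
print(f"MML = {mml(pmf):.4f}   (mean fraction of methylated CpGs)")
print(f"NME = {nme(pmf):.4f}   (entropy / log2(L+1), in [0, 1])")
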