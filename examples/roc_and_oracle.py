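"""ROC/AUC of the detector and a cross-check against the DFT oracle.

The ROC curve sweeps the call threshold over the normalized energy profile
and scores every nucleotide against the planted annotation. The independent
sliding-window DFT oracle measures period-3 spectral power directly; both
should rank coding positions above noncoding ones.
"""

import numpy as np

import wavexon as wx

seq, truth = wx.generate_gene(wx.GeneSpec(seed=1))
result = wx.run_pipeline(seq)

curve = wx.roc_curve(result.normalized, truth)
print(f"{seq.id}: nucleotide-level AUC = {curve.auc:.4f} "
      f"({len(curve.points)} threshold points)")

oracle = wx.period3_strength(seq, window=99)
mask = truth.mask(len(seq))
ratio = oracle.values[mask].mean() / oracle.values[~mask].mean()
print(f"DFT oracle: mean period-3 power inside exons is {ratio:.1f}x the intron level")
print("(AUC near 1.0 = the energy profile separates coding from noncoding;")
print(" the oracle ratio confirms the planted period-3 signal independently.)")
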