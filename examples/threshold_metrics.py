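"""The eight threshold metrics from segment-level confusion counts.

A benchmark-style gene has 5 exons and 5 intervening/flanking noncoding
units. At a permissive threshold all 5 exons are detected but 2 noncoding
units are falsely called; at a strict threshold one exon is missed but
nothing false is called. The metrics below follow directly from the counts.
"""

import wavexon as wx

for name, counts in [
    ("permissive (tp=5 fp=2 fn=0 tn=3)", wx.ConfusionCounts(5, 2, 0, 3, "segment")),
    ("strict     (tp=4 fp=0 fn=1 tn=5)", wx.ConfusionCounts(4, 0, 1, 5, "segment")),
]:
    r = wx.compute_metrics(counts)
    print(name)
    for key, value in r.as_dict().items():
        print(f"  {key:>22}: {'undefined' if value is None else f'{100 * value:6.2f}%'}")

print("Error rate is 1 - accuracy; FDR = 1 - positive precision;")
print("FOR = 1 - negative precision. Undefined marks a 0/0 ratio.")
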