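"""Explain one prediction with SHAP attributions down to codon resolution.

Trains a small model on synthetic transcripts, explains one held-out
mRNA-like sequence against a mixed background, and compares the mean
|codon attribution| inside the planted motif with the rest of the
sequence — the synthetic analogue of spotting a protein domain. Also
renders the blue/red color-track figure (blue = toward lncRNA,
red = toward mRNA) to attribution.png.
"""

import numpy as np

import xlnc1d as x
from xlnc1d import explainer

spec = x.SyntheticSpec(
    n_per_class=200, length_range=(200, 600), motif=x.DEFAULT_MOTIF,
    motif_rate=1.0, seed=21,
)
records, annotations = x.generate_dataset(spec)
anns = {a.seq_id: a for a in annotations}
train_recs, test_recs = x.stratified_split(records, x.SplitSpec(test_fraction=0.2, seed=21))
train_set = x.encode_dataset(train_recs, 600)

config = x.ModelConfig.scaled_down(seed=3)
model = x.train(x.build_model(config), train_set, config)

target = next(r for r in test_recs if r.label == x.MRNA)
target_set = x.encode_dataset([target], 600)
background = x.select_background(train_set, n_per_class=8, seed=3)
[attr] = x.compute_shap(model, background, target_set, n_steps=25)

p = x.predict(model, target_set)[0]
print(f"{target.id}: p(lncRNA) = {p.p_lncRNA:.3f} -> called {p.predicted_label}")
print(f"additivity: sum(SHAP) + base = {attr.values.sum() + attr.base_value:.3f} "
      f"(base over background = {attr.base_value:.3f})")

track = x.collapse_to_nucleotide(attr)
track.values = track.values[: attr.seq_length]
codons = x.codon_aggregate(track)

a = anns[target.id]
frame = a.start % 3
vals = np.abs(codons.frames[frame])
first = (a.start - frame) // 3
n_codons = (a.end - a.start) // 3
inside = vals[first : first + n_codons].mean()
outside = np.concatenate([vals[:first], vals[first + n_codons :]]).mean()
print(f"planted motif at {a.start}-{a.end} (frame {frame}): "
      f"mean |codon SHAP| inside = {inside:.4f}, outside = {outside:.4f}")
# inside >> outside means the model's evidence concentrates on the motif,
# i.e. the attribution recovers the planted ground truth.

meta = x.plot_attribution(codons, target, "attribution.png")
n_red = sum(s.color == "red" for s in meta.segments[frame])
print(f"wrote attribution.png ({n_red} mRNA-leaning codons in frame {frame})")
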