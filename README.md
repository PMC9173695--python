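# xlnc1d

Classify transcripts as **long non-coding RNA (lncRNA)** or
**protein-coding transcript (mRNA)** directly from the nucleotide sequence
with a one-dimensional convolutional neural network, and *explain* each
call with additive (SHAP) attributions at nucleotide, codon
(three reading frames) and k-mer resolution.

The package is for computational biologists who want a transparent
coding-potential classifier: instead of hand-crafted features (ORF length,
hexamer score, ...), a 1D CNN reads the one-hot encoded sequence itself,
and the attribution pipeline shows *which* subsequences drove each
decision — protein-domain-like regions pull toward mRNA, stop-codon-rich
stretches pull toward lncRNA.

## The model

Sequences of 200–3,000 nt are one-hot encoded (channels A, C, G, T;
ambiguity codes as zero rows) and right-padded. The classifier is

```
3 × [ conv1d(kernel 57, stride 1) → ReLU → max-pool(2) → dropout 0.3 ]
→ flatten → dense(256) → ReLU → dropout 0.5
          → dense(256) → ReLU → dropout 0.5 → softmax(2)
```

trained with SGD (momentum 0.9, learning rate 0.01, batch 128, 120
epochs) on two-class cross-entropy, lncRNA being the positive class.
A scaled-down profile (16 filters, 600-nt input, 25 epochs, batch 32,
dropout off)
makes the whole pipeline run on a laptop CPU; the full architecture is one
config flag away.

Attributions are SHAP values for the lncRNA softmax output, estimated by
expected gradients over a background set (default 175 sequences per
class): for background b, the input gradient of p(lncRNA) is integrated
along the path b → x and weighted by (x − b), then averaged over
backgrounds. Additivity holds: Σ attributions + base ≈ p(lncRNA).
Channel sums give one value per nucleotide; sums of nucleotide triples
give codon tracks in the three reading frames; |window-sum| means grouped
by k-mer give the impact tables. A built-in generator produces synthetic
transcripts with known ground truth (a single long ORF with an optional
planted motif vs i.i.d. nucleotides) so that motif recovery is testable
without downloads.

## Worked example

```bash
python examples/simulate_and_train.py
```

trains the scaled-down model on 300 synthetic transcripts and prints:

```
trained 25 epochs; final training accuracy 1.000
held-out confusion: TP=50 FP=1 TN=49 FN=0
held-out metrics (percent): {'accuracy': 99.0, 'sensitivity': 100.0,
'specificity': 98.0, 'precision': 98.04, 'f1': 99.01, 'auc': 1.0}
```

i.e. the synthetic class contrast is essentially separable at this scale.
`examples/explain_transcript.py` explains one held-out mRNA-like
transcript and prints

```
mrna_00074: p(lncRNA) = 0.000 -> called mRNA
additivity: sum(SHAP) + base = 0.008 (base over background = 0.500)
planted motif at 154-211 (frame 1): mean |codon SHAP| inside = 0.0334, outside = 0.0019
```

— the attribution mass concentrates ~18x inside the planted motif, the
synthetic analogue of highlighting a protein domain.
`examples/evaluate_predictions.py` reproduces the published nine-tool
benchmark metric table from its confusion counts — the first row works
out to accuracy 94.53 and F1 95.38.

The same workflow is available from the shell:

```bash
xlnc1d simulate --n-per-class 100 --motif GATTACAGATTACA... --motif-rate 1.0 --out sim/
xlnc1d preprocess --fasta sim/sequences.fasta --labels sim/labels.tsv --out prep/
xlnc1d train --data prep/train.npz --out model.npz
xlnc1d predict --model model.npz --fasta sim/sequences.fasta --out pred.tsv
xlnc1d explain --model model.npz --fasta some.fasta --background prep/train.npz --out exp/
xlnc1d evaluate --pred pred.tsv --labels sim/labels.tsv --out report/
```

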