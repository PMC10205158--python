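# lexrsa

Searchlight representational similarity analysis (RSA) of lexical similarity
models, with partial-correlation RSA, permutation cluster-extent inference,
and a synthetic fMRI generator that plants known representational geometry.

## The problem

How a word's meaning is organised in the brain can be probed by comparing two
similarity structures over a set of stimulus words: a **model RDM** (a
word-by-word similarity matrix predicted by some account of word meaning) and
a **neural RDM** (the similarity of the brain activity patterns the words
evoke).  Different accounts make genuinely different predictions:

- **affective space** — the Euclidean distance between words in the 3-D space
  of valence, dominance and arousal ratings (1–7 scale), converted to a
  similarity by `s = 1 − d/d_max`;
- **co-occurrence embeddings** — cosine similarity between word2vec-style
  vectors (e.g. 300-dim cBOW);
- **association-based embeddings** — cosine similarity between vectors
  derived from free word-association data;
- **phonology** — length-normalised Levenshtein similarity of phonological
  transcriptions, and the absolute difference in phonological neighbourhood
  density;
- **taxonomy** — Wu–Palmer similarity
  `WPsim(a, b) = 2·depth(LCS) / (depth(a) + depth(b))`.

The package implements the full analysis path for asking where in the brain
each model's structure is expressed, and whether two models' effects are
*independent*:

1. **Model level** — build all similarity matrices from plain tabular inputs;
   correlate them (the correlogram); compare two dependent overlapping
   correlations with the **Pearson–Filon z**,

   ```
   z = (r12 − r13)·√n / √((1−r12²)² + (1−r13²)² − 2k),
   k = r23(1 − r12² − r13²) − ½ r12 r13 (1 − r12² − r13² − r23²);
   ```

   check stimulus matching with a one-way ANOVA computed from per-group
   summary statistics alone.
2. **Subject level** — motion QC by framewise displacement (runs with max
   FD > 1 mm are dropped whole); model-free single-trial activation as the
   area under the BOLD curve 2–8 s post onset; pooling over trials, tasks and
   modalities into one pattern per word; a whole-brain **searchlight** (the
   k = 200 nearest grey-matter voxels per center) computing centred cosine
   neural RDMs and their plain or **partial Spearman** correlation with model
   RDMs; Fisher r-to-z and smoothing.
3. **Group level** — voxelwise one-sample and paired t tests across subjects;
   cluster-extent familywise-error control by **sign-flipping permutation**
   (18-connected clusters at voxelwise p < 0.001, corrected p from the
   max-cluster-size null).
4. **Synthetic data** — a generator emulating the reference design (66 nouns
   in 3 valence classes of 22; 8 runs × 77 trials; ISI 8.25 s; TR 1 s) whose
   signal regions carry condition patterns with an exactly planted similarity
   structure, so the whole pipeline can be validated by parameter recovery.

## Worked example

`examples/searchlight_pipeline.py` simulates eight subjects whose signal
region expresses only model A (co-occurrence-like embeddings) while model B
(the affective space) correlates with A at ≈ 0.065, then runs the full
pipeline and group inference:

```
corr(A, B) between model RDMs: 0.058

Group-mean searchlight Spearman rho (inside / outside the region):
     A: +0.139 / +0.012
   A|B: +0.139 / +0.012
     B: +0.008 / +0.003
  -> A is expressed in the region; partialling B changes nothing; B is flat.

Cluster-extent FWE (sign-flip, 256 permutations), model A:
 size  p_fwe  peak_i  peak_j  peak_k  peak_x_mm  peak_y_mm  peak_z_mm  peak_t
  535  0.004       6       8       8       12.0       16.0       16.0  77.224
```

Model A's effect is confined to the planted region, survives partialling out
model B unchanged (the independence signature), and B shows no effect — while
the cluster test localises A's effect with a corrected p-value.  The other
examples cover the model-level statistics (`examples/word_models.py`) and
motion QC plus tSNR (`examples/motion_qc.py`).

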