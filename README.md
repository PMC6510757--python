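# stemloop

Recognition of 3′-end stem-loop structures in retrotransposon-like DNA
sequences with random-forest models.

LINE-1 (L1) and Alu retrotransposons carry a hairpin — a stem-loop — at
their 3′ end.  The sequence of that region is poorly conserved, yet the
*structure* is nearly universal, which suggests it is what the L1
retrotransposition machinery actually recognizes.  `stemloop` provides the
complete computational pipeline for studying this signal:

1. **Detection** — find approximate stem-loops (inverted repeats) under
   explicit constraints: stem 10–20 bp, loop ≤ 10 nt, up to 5 mismatches in
   the stem, at most one bulge of ≤ 3 nt per arm, and select the best
   hairpin fully contained in the terminal 50 bp of each element.
2. **Negative class** — Altschul–Erikson dinucleotide shuffling, which
   preserves the exact multiset of overlapping dinucleotides (and therefore
   mononucleotide composition and sequence ends), so models cannot win on
   low-order composition alone.
3. **Encoding** — two feature families:
   * *sequence-based*: overlapping di-/trinucleotide frequencies of the
     terminal window (16 + 64 = 80 features);
   * *structure-based*: 134 features per hairpin — the 9 dinucleotide steps
     of the 10 loop-proximal stem positions × 10 physico-chemical/helical
     properties (shift, slide, rise, tilt, roll, twist, enthalpy, entropy,
     free energy, hydrophilicity; 90 features), one-hot encodings of loop
     positions LP0–LP4 (20), and bulge slots LB0–LB2/RB0–RB2 (24).
4. **Classification** — Random Forests (2000 trees by default) with
   stratified cross-validation, ROC/PR curves, impurity-based feature
   importances and top-10 summaries, plus cross-application of trained
   models to foreign sequence sets (recognized fraction at a probability
   threshold).
5. **Synthetic cohorts** — a seeded generator plants hairpins with
   controllable stem composition, loop motif, mismatches and bulges inside
   the terminal window, so every stage is testable without external data.

Intended users: computational biologists studying mobile-element biology or
functional RNA/DNA secondary structure, and anyone needing a reproducible
inverted-repeat detector with a machine-learning readout.

## Worked example

```python
import stemloop as sl

# 80 sequences, each with a hairpin whose stem alternates A/G (a strong
# dinucleotide bias), planted in the last 50 nt of a 60-mer
spec = sl.SyntheticSpec(n_sequences=80, seq_length=60, stem_length_range=(14, 18),
                        stem_dinuc_bias={"GA": 25.0, "AG": 25.0}, seed=11)
records, truths = sl.generate(spec)

# detect -> shuffle -> encode -> train, all from one seed
result = sl.run_pipeline(records, scheme=sl.SCHEME_STRUCTURE,
                         n_trees=500, cv_folds=5, seed=11)
r = result.report
print(f"AUC      {r.auc_mean:.3f} +/- {r.auc_std:.3f}")
print(f"accuracy {r.accuracy_mean:.3f}   precision {r.precision_mean:.3f}   recall {r.recall_mean:.3f}")
print("top-5 features:", ", ".join(r.top10[:5]))

ann = result.positive_annotations[0]
print(f"first hairpin: stem {ann.stem_length} bp, loop {ann.loop_string!r}, "
      f"mismatches {ann.mismatch_count}, span {ann.span}")
```

Output:

```
AUC      0.909 +/- 0.048
accuracy 0.825   precision 0.850   recall 0.787
top-5 features: LS4:hydrophilicity, LS3:hydrophilicity, LS2:hydrophilicity, LS6:hydrophilicity, LS8:hydrophilicity
first hairpin: stem 17 bp, loop 'AATTC', mismatches 0, span (9, 49)
```

Reading: the structure-based forest separates planted hairpins from their
dinucleotide-shuffled counterparts with mean cross-validated AUC 0.909, and
the most important features are hydrophilicity channels of stem positions
(`LS<i>:<property>` = i-th dinucleotide step counted from the loop) —
exactly where the planted A/G bias lives.  Feature names `LP<i>:<base>` and
`LB/RB<i>:<base>` refer to loop and bulge positions.

## Command line

```bash
stemloop simulate --n 100 --length 300 --seed 1 --out cohort.fa --truth truth.tsv
stemloop detect   --fasta cohort.fa --end 3prime --out hairpins.tsv --bed hairpins.bed
stemloop shuffle  --fasta cohort.fa --seed 17 --out shuffled.fa
stemloop encode   --fasta cohort.fa --scheme structure --out features.tsv
stemloop pipeline --fasta cohort.fa --scheme structure --seed 1 --out run/
stemloop apply    --model run/model.joblib --fasta other.fa --out scored.tsv
```

Real transposon sets (full-length L1/Alu FASTA, processed pseudogenes,
mRNA 3′ regions) can be supplied to the same commands; outputs are
TSV/BED6/JSON with 0-based half-open coordinates.

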