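# afpid

Identification of antifreeze proteins (AFPs) from primary sequence, and
residue-level flagging of candidate ice-binding residues — no structures
required.

The pipeline:

1. **Coding schemes** (`afpid.features`): protein sequences are encoded as
   n-peptide composition vectors under the original or reduced amino-acid
   alphabets (`afpid.alphabets`): plain composition `C`, partitioned
   compositions `Xk`, g-gap dipeptide compositions `Dg`, reduced-alphabet
   partitioned compositions (`H3X5`, `P3X5`, `S2X5`), and sliding-window
   neighborhood compositions `Wl`. The default jury uses 13 schemes:
   `C, X5, X6, X7, D0, D1, D3, D6, H3X5, P3X5, S2X5, W7, W11`.
2. **Per-scheme classifiers** (`afpid.scheme_classifier`): one RBF-kernel
   SVM per scheme, hyperparameters grid-searched by internally
   cross-validated MCC, class imbalance handled by a positive-class weight.
3. **GA feature selection** (`afpid.ga_select`): a genetic algorithm prunes
   each scheme's attributes, maximizing internal-CV MCC with ties broken by
   fewer false positives, then fewer attributes.
4. **Jury voting** (`afpid.voting`): sequence-level calls by strict-majority
   voting over the scheme classifiers; residue-level vote maps credit every
   residue in the footprint of every occurrence of a GA-selected attribute.
   Tiers: red >= 6 votes, yellow 4–5, gray <= 3.
5. **Evaluation** (`afpid.metrics`): per-class accuracy, overall accuracy,
   precision, Matthews correlation coefficient.
6. **Homology context** (`afpid.homology`): global alignment percent
   identity (Needleman–Wunsch, affine gaps) and SI-binned identification
   rates.
7. **Synthetic benchmarks** (`afpid.synthetic`): planted-motif generators
   (e.g. `LT` and `TxxT` planted into uniform background) with recorded
   ground truth, so the whole pipeline is testable offline.

## CLI

```sh
# generate a labeled planted-motif benchmark
afpid simulate --n-pos 200 --n-neg 200 --seed 0 --out bench/

# train a jury (GA selection on by default); writes a directory archive
afpid train bench/sequences.fasta bench/labels.tsv \
    --archive model/ --schemes C,D0,D2 --seed 0

# sequence-level verdicts and per-residue vote maps
afpid predict bench/sequences.fasta --archive model/ --out verdicts.tsv
afpid votes   bench/sequences.fasta --archive model/ --out votes.tsv

# metrics report from verdicts + labels
afpid evaluate verdicts.tsv bench/labels.tsv
```

Every output file begins with a comment header recording the version, seed
and configuration hash. The archive is a directory containing
`manifest.json` (scheme specs, masks, hyperparameters, training
fingerprints) and one pickled model per jury member; `predict` refuses
archives written by a different package version.

## Notes and documented approximations

- The exact residue memberships of the 4/7/8-group alphabets (`F`, `S`,
  `E`) are not fixed by a single convention; the bundled defaults live in
  `src/afpid/data/alphabet_groups.tsv` and every alphabet can be overridden
  with `--alphabet-table` (TSV of name, group symbol, residues).
- `Dg` counts pairs with exactly g intervening residues, following the
  `a(x)_g b` definition (so `TxxT` belongs to `D2`).
- Window compositions exclude the center residue and truncate windows at
  the sequence ends.
- Vote-tier boundaries close the published legend's gaps: exactly 6 votes
  is red, exactly 3 is gray.
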