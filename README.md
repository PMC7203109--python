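# rbrid

Locate RNA-binding regions (RBRs) of a protein from ±4SU crosslinking
mass-spectrometry, the RBR-ID strategy.

## The problem and the method

Cells (or in vitro binding reactions) are supplied with 4-thiouridine
(4SU), a photoactivatable uridine analog incorporated into RNA. 312-nm UV
crosslinks 4SU to protein residues in direct contact with the RNA. A
crosslinked peptide carries an RNA adduct and is no longer detected at its
normal mass, so when the sample is digested with trypsin and quantified by
label-free MS, peptides from RNA-binding regions are **depleted** in the
+4SU runs relative to −4SU controls. This package turns replicated ±4SU
peptide intensity tables into residue-level maps of that depletion:

1. **Normalize** — each MS run's intensities are divided by the run's total,
   removing loading and acquisition differences.
2. **Per-peptide statistics** — for each peptide, condition means m₊ and m₋
   (a condition observed as all zeros gets the imputed mean
   0.5 · min over the dataset of the positive condition means), the
   depletion ratio log₂(m₊/m₋), a two-sided unpaired Student's *t* test
   P-value, and the RBR-ID score

   score = −log₂(m₊/m₋) · (log₁₀ P)²

   which is positive for depleted peptides and grows with both effect size
   and reproducibility. Peptides with P < 0.1 and ratio < 1 are flagged
   significantly depleted.
3. **Residue projection** — each residue's score is the sum of the scores of
   all peptides overlapping it (exact substring matching, 1-based inclusive
   coordinates).
4. **Smoothing** — the residue track is smoothed with Friedman's
   variable-span supersmoother (supsmu), implemented here from scratch:
   local linear fits at spans 0.05/0.2/0.5 of the sequence, per-residue span
   selection by cross-validated residuals, interpolation between the
   bracketing fits.
5. **Segment calling** — maximal runs of residues whose smoothed score
   exceeds a quantile threshold (default 0.85 over covered residues) become
   candidate RBR segments, after gap merging (≤5 aa) and a minimum length
   (10 aa).

A synthetic-experiment generator (random protein → tryptic digest →
log-normal abundances, batch factors, multiplicative noise,
intensity-dependent dropout, and a planted RBR with a known depletion
factor δ) provides ground truth for end-to-end validation.

## Worked example

`examples/02_simulate_and_recover_rbr.py` plants an RBR at residues
1100–1399 of a 2500-aa synthetic protein, with overlapping peptides keeping
δ = 50% of their intensity in the 8 crosslinked runs, and runs the full
analysis:

```
simulated 325 tryptic peptides x 16 MS runs
significantly depleted peptides (P < 0.1, ratio < 1): 45
called segment 1047-1419 (peak score 32.8, mean 23.8)
planted RBR 1100-1399: detected=True, Jaccard=0.80, center error=16.5 residues
```

The called segment covers the planted region (Jaccard 0.80 residue-set
overlap) and its midpoint lands within 17 residues of the truth. The other
examples score a 4-peptide table by hand-sized steps
(`01_score_a_peptide_table.py`) and contrast the supersmoother with a
fixed-bandwidth smooth (`03_supersmoother.py`).

The same analysis is available from a shell:

```sh
rbrid simulate --out sim --seed 11
rbrid run --table sim/peptides.tsv --design sim/design.tsv \
          --fasta sim/protein.fasta --out results
```

`rbrid run` writes per-peptide statistics, the raw and smoothed per-residue
score tracks, called segments (all TSV), a track plot, and a JSON report
with stage-by-stage counts.

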