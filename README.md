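# coevocontact

Residue–residue contact prediction from sequence coevolution.

From a multiple sequence alignment, the pipeline computes clustered
sequence weights, pseudocounted single/pair frequency tables, a
site–state covariance matrix, and couplings via one of two routes:

* **evfold profile** — dense covariance inversion (mean-field direct
  coupling analysis) over 20 states per column;
* **psicov / psicov-sd profiles** — shrinkage to positive definiteness
  followed by L1-penalized sparse inverse covariance estimation
  (graphical lasso), with optional precision-matrix density targeting
  and a cooperative time limit.

Couplings are collapsed to per-pair block norms (Frobenius or L1),
average-product corrected, separation-filtered and ranked.  A
CASP-style evaluator derives true contacts from PDB structures
(Cβ–Cβ < 8 Å, Cα for glycine) and reports top-L/n precision per
separation band.  A synthetic generator plants pairwise couplings and
redundancy in Gibbs-sampled alignments so every stage is testable
offline.

## Command line

```sh
# mean-field DCA mode, aligned FASTA on stdin, TSV on stdout
coevocontact --parprof evfold < family.afa > contacts.tsv

# sparse-inverse mode with explicit overrides
coevocontact --parprof psicov --clustpc 62 --density 0.03 \
    --icme-timeout 1800 -o contacts.tsv family.aln
```

Input: aligned FASTA or flat format (one sequence per line, no
headers); the **first sequence is the target** and its columns are kept
as-is (target gap columns are not removed).  Output: one contact per
line, `i  res_i  j  res_j  raw  corrected`, 1-based positions, sorted
by descending corrected score.  The run log (Meff, kept columns,
shrinkage α, final ρ, density, per-stage timings) goes to stderr.

Exit codes: `0` success, `2` insufficient total alignment weight
(Meff below `--min-meff`, default 1.5), `3` inverse covariance
estimation timeout, `1` other errors.

Profile constants (clustering thresholds, pseudocounts, ρ, density …)
are reconstructions of the recommended parameterizations of the
original tools — the canonical values were never published — and are
echoed in the run log for transparency.

Conventions worth knowing:

* identity = matches / full alignment length; gap–gap is a match,
  gap–residue a mismatch (gap behaves as a 21st symbol);
* all non-canonical residue codes (B, J, O, U, X, Z, lowercase, `.`)
  are pooled into the gap state;
* the predictor filter is `j − i ≥ mincontsep` while the evaluator's
  separation bands use the strict `j − i > sep`, matching the two
  conventions used in the field.

## Library

```python
from coevocontact.cli import resolve_profile, run
from coevocontact.synthetic_data import PlantedModel, sample_alignment

aln = sample_alignment(PlantedModel(L=30, M=2000, seed=1,
                                    coupled_pairs=((7, 22, 2.0),)))
contacts, log = run(resolve_profile("evfold"), aln)
```

Modules: `msa_io` (formats, encoding), `weighting` (cluster weights,
Meff), `statistics` (frequencies, covariance), `inference` (inversion,
graphical lasso), `scoring` (block norms, APC, ranking), `evaluation`
(contact maps, precision), `synthetic_data` (planted-coupling
generator), `cli` (profiles and pipeline).

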