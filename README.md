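# lacunaseq

Fractal lacunarity analysis of mitochondrial-genome mutation load.

Point mutations of human mtDNA — homoplasmic substitutions affecting every
mtDNA copy, and heteroplasmic ones affecting only a fraction — act like gaps
scattered through the nucleotide sequence. `lacunaseq` quantifies their
collective effect as a single texture index: the mtDNA sequence is rendered
as a Chaos Game Representation (CGR) image, the gappiness of that image is
measured by gliding-box lacunarity, and a hyperbola model is fitted to the
lacunarity curve. The fitted amplitude **β** is a per-subject biomarker that
can be compared between cohorts (e.g. Alzheimer's disease patients vs
age-matched controls) or screened against a cutoff. The intended users are
bioinformaticians and geneticists working with resequencing-array base
calls of mitochondrial genomes.

## Method

1. **Sequence reconstruction.** A subject's sequence is the reference (e.g.
   the rCRS) with per-position base calls applied. A heteroplasmic call is a
   single degenerate IUPAC symbol (`m` = `a` or `c`, …) covering the mixed
   alleles.
2. **Weighted CGR.** Every length-*L* window of the sequence maps to one
   cell of a 2^L × 2^L matrix by recursive quadrant addressing (base layout
   `[[a,c],[g,t]]`). A window containing degenerate symbols is expanded into
   all pure strings it covers, each incrementing its cell by weight
   1/(number of expansions): `tamcg` → `taacg`, `taccg` at weight ½.
   Total matrix mass is always `len(S) − L + 1`.
3. **Lacunarity.** The matrix is min–max scaled to [0, 1] and passed through
   a logistic threshold `J = 1/(1 + exp(−k(I − σ)))` (defaults k = 7,
   σ = 0.7). A b×b box glides over the image with stride 1; with box-mass
   moments `Z_q = Σ_j M_j^q n(M_j, b)/N(b)` the lacunarity is
   `Λ(b) = Z₂/Z₁² ≥ 1`, evaluated for every integer b from b_min (default 3)
   to half the image side.
4. **Hyperbola fit.** `Λ(b) ≈ β·b^(−α) + γ` by bounded least squares;
   β is the biomarker, α relates to the fractal dimension, γ is the
   asymptote.
5. **Cohort statistics.** Group means are compared with a pooled-variance
   one-tailed Student t-test; subjects with β at or below a cutoff (fixed,
   or the whole-sample median) are classified as positive.

## Worked example

All inputs can be simulated, so the full pipeline runs without any
downloads:

```sh
lacunaseq simulate sequence --length 16569 --seed 42 --forbid cg --out ref.fa
lacunaseq simulate mutations --reference ref.fa \
    --n-homoplasmic 14 --n-heteroplasmic 3 --seed 42 --out calls.tsv
lacunaseq run --reference ref.fa --calls calls.tsv \
    --subject-id subj01 --out results/
```

which prints

```
16569 bp -> ref.fa
17 calls -> calls.tsv
subj01: beta=4.0146 (14 homoplasmic, 3 heteroplasmic)
```

The first command draws a CpG-depleted random sequence with human-mtDNA
base composition (its CGR shows the Sierpinski-triangle-like pattern of
real mtDNA). The second injects 14 homoplasmic and 3 heteroplasmic calls —
an AD-scale mutation load. The `run` command chains calls → CGR (32 × 32 at
the default L = 5) → sigmoid → Λ(b) for b = 3…16 → hyperbola fit, and
`results/subj01.json` holds the fitted triplet:

```json
{
  "alpha": 0.6634621793167623,
  "beta": 4.014588600882286,
  "gamma": 0.5969049361528475,
  "residual_norm": 0.007204176265215376,
  "converged": true,
  "n_points": 14,
  "r_squared": 0.9963094705337164
}
```

β ≈ 4.01 is this subject's lacunarity amplitude; R² ≈ 0.996 shows the
hyperbola model tracks the measured curve closely. Mutations lower β
relative to the unmutated reference, so smaller values indicate a heavier
mutation load. `lacunaseq batch` processes a manifest of subjects and
`lacunaseq cohort` compares the fitted β values between two groups.

## Layout

- `src/lacunaseq/seqio.py` — FASTA / call-table I/O, sequence reconstruction
- `src/lacunaseq/cgr.py` — weighted CGR matrix and mutation report
- `src/lacunaseq/lacunarity.py` — sigmoid preprocessing, gliding-box Λ(b)
- `src/lacunaseq/hypfit.py` — hyperbola-model least-squares fit
- `src/lacunaseq/cohort.py` — t-test, cutoff classification
- `src/lacunaseq/synthetic.py` — sequence/mutation/image simulators
- `src/lacunaseq/pipeline.py`, `cli.py` — per-subject pipeline, batch driver, CLI

See `docs/methods.md` for the modelling choices and their rationale.
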