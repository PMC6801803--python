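# shapefold

Chemical-probing-directed secondary structure inference for long RNAs,
built for the workflow used to map lncRNA structures such as the ~683-nt
SWI/SNF-binding lncRNA studied with SHAPE-MaP and DMS-MaP:

1. **SHAPE-directed folding** — normalized reactivities enter a
   nearest-neighbour thermodynamic model as Deigan pseudo-free energies
   `ΔG(i) = m·ln(r_i + 1) + b` per stacked nucleotide; the engine computes
   the MFE structure, a bounded suboptimal ensemble of candidate models
   (Wuchty-style), and McCaskill partition-function base-pair
   probabilities `P(i,j)`.
2. **Shotgun (3S) analysis** — fragments probed in isolation are compared
   with the matching region of the full-length profile by Pearson `r`;
   `r ≥ 0.85` calls an independent subdomain, and candidate models placing
   base pairs across an independent fragment's boundary are eliminated.
3. **Jackknife confidence** — 100 mock datasets, each with 10% of the
   measured reactivities masked to "no data", are refolded; a nucleotide's
   confidence is the percentage of refolds in which its pairing partner
   matches the chosen model.
4. **Shannon entropy** — `S(i) = −Σ_j P(i,j)·log₁₀ P(i,j)`; runs where
   smoothed entropy stays below 0.2 and smoothed confidence above 70%
   mark well-defined structural domains.
5. **DMS validation** — reactivities of single-stranded A/C are binned
   (low < 0.4 ≤ mid ≤ 0.85 < high), and the agreement statistic is the
   percentage of highly reactive A/Cs the model places in loops or at
   helix termini.
6. **Covariation** — a structure mapped onto a Stockholm alignment is
   screened with mutual information plus APC correction and a
   within-column permutation null with Benjamini–Hochberg FDR.

Because raw probing data for such transcripts are rarely deposited, the
package includes a first-class synthetic-data generator
(`shapefold.synthetic`) producing ground-truth structures, reagent-faithful
SHAPE/DMS profiles with dropout, independently folded fragments, and
homolog alignments with designed compensatory mutations — so every stage of
the pipeline is testable end to end.

## Worked example

```python
from shapefold import (SimulationParams, simulate_rna, simulate_reactivities,
                       fold_mfe, jackknife_confidence, partition_function,
                       shannon_entropy, find_well_defined_regions,
                       structure_stats)

params = SimulationParams(seed=7)
rna = simulate_rna(200, seed=7, params=params)          # ground truth
shape = simulate_reactivities(rna.structure, "SHAPE", params)

model = fold_mfe(rna.sequence, shape)                   # SHAPE-directed MFE
stats = structure_stats(model)
truth = set(rna.structure.pair_list())
sens = 100 * len(truth & set(model.pair_list())) / len(truth)
print(f"energy {model.energy:.1f} kcal/mol, "
      f"{stats['percent_paired']:.0f}% paired, {stats['n_helices']} helices")
print(f"sensitivity vs ground truth: {sens:.1f}%")

conf = jackknife_confidence(rna.sequence, shape, model, n_reps=100, seed=7)
ent = shannon_entropy(partition_function(rna.sequence, shape))
for reg in find_well_defined_regions(conf, ent):
    print(f"well-defined region {reg['start']}-{reg['end']}: "
          f"confidence {reg['mean_confidence']:.1f}%, "
          f"entropy {reg['mean_entropy']:.2f}")
```

prints

```
energy -105.4 kcal/mol, 57% paired, 13 helices
sensitivity vs ground truth: 94.1%
well-defined region 1-200: confidence 93.8%, entropy 0.07
```

The directed fold recovers 94% of the ground-truth pairs (the
reactivity-free fold of the same sequence recovers far less — the latent
stability perturbation used by the generator makes the truth recoverable
from data, not from thermodynamics alone), and the whole molecule scores
as well-defined because the profile was generated cleanly; ambiguous
stretches can be injected with `scramble_region`.

A command-line interface mirrors the library (`shapefold fold`,
`shotgun`, `confidence`, `entropy`, `domains`, `dms`, `conserve`,
`simulate`, and `run` for the full pipeline from a JSON config; every run
writes a manifest from which the outputs are byte-reproducible).

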