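# Methods

This note records the models, parameter choices and numerical conventions
behind `shapefold`, and what its synthetic benchmarks do and do not show.

## Thermodynamic model

Folding is over pseudoknot-free nested structures with canonical pairs
(AU, UA, GC, CG, GU, UG) and hairpin loops of at least three nucleotides.
Lonely (isolated) pairs are allowed. The free energy of a structure is the
sum over its loops:

- **Stacks.** A simplified Turner-like table: the stack of pairs p over q
  costs `−(s(p) + s(q))` kcal/mol with pair strengths `s(CG/GC) = 1.5`,
  `s(AU/UA) = 0.9`, `s(GU/UG) = 0.45`. The additive form is symmetric
  under strand reversal by construction. The table lives in
  `EnergyModel.stack` and can be replaced wholesale (e.g. by Turner 2004
  values); the pipeline's logic does not depend on the parameter vintage.
- **Loops.** Hairpin, bulge and internal-loop initiation penalties are
  tabulated from anchors (5.4 at hairpin-3, 3.8 at bulge-1, 1.7 at
  internal-2) and grown with the Jacobson–Stockmayer entropy term
  `1.75·RT·ln(n/n₀)`. Internal-loop asymmetry costs `0.5·|n₁−n₂|`, capped
  at 3.0 (Ninio-style). Interior loops are capped at 30 unpaired
  nucleotides in the search, the standard restriction.
- **Multibranch loops.** Linear model `a + b·(branches)` with `a = 3.4`,
  `b = 0.4` per branch (closing helix included) and zero cost per
  unpaired nucleotide (`c = 0`), which also keeps the outside algorithm
  simple.
- **Temperature** 310.15 K; `RT = 0.6163` kcal/mol.

Not modelled (out of scope by design): pseudoknots, coaxial stacking,
dangling ends, terminal-AU penalties, sequence-dependent loop bonuses,
tertiary structure.

## Probing pseudo-energies

A reactivity `r ≥ 0` at nucleotide `i` contributes
`ΔG(i) = m·ln(r+1) + b` with defaults `m = 2.6`, `b = −0.8` kcal/mol —
the Deigan convention — added once for each helix stack the nucleotide
participates in (interior nucleotides of a helix are in two stacks and
receive the term twice). `NO_DATA` contributes zero, never a zero
reactivity. The identical term enters the MFE recursion, the suboptimal
generator, the partition function and the explicit loop-decomposition
scorer, which is what makes the exhaustive-enumeration oracle meaningful.

Reactivity normalization is the 2%/8% rule: defined values sorted
descending, top 2% excluded, the vector divided by the mean of the next
8%. The operation is scale-invariant and idempotent. Negative raw values
are clamped to zero on input; the external NO_DATA sentinel is −999.

## Dynamic programs

The grammar (V for pair-closed intervals, M1 for a multiloop branch with
trailing unpaired, M for a ≥1-branch multiloop segment split at the last
branch start, W for the exterior) is **non-redundant**: every structure
has exactly one derivation. The same recursions therefore serve

- the MFE fill and a deterministic traceback (ties prefer unpaired, then
  the first candidate in a fixed scan order — outputs are
  bit-reproducible);
- **Wuchty-style complete suboptimals**: best-first expansion of partial
  derivations whose priority is the exact minimum energy of their
  completions, emitting distinct structures in non-decreasing energy
  order until `max_models` (default 20) or the window (default 20% of
  |MFE|) is exhausted;
- **McCaskill partition function**: Boltzmann-sum analogue of the same
  grammar, rescaled per nucleotide by `exp(−MFE/(n·RT))` so the
  recursion stays finite to n of a few thousand. Pair probabilities come
  from an outside pass; the multiloop outside sum is kept at O(n³) with
  two running tables (D, E) that accumulate, for every finalized
  enclosing pair, the weight seen by a branch with and without further
  branches on its left.

Verification is by exhaustive enumeration at small n (≤ 20): all nested
structures are generated by direct recursion and scored by the explicit
loop decomposition; MFE energies agree exactly and pair probabilities to
1e−6 (see the acceptance suite). Kernels are numba-compiled;
n = 683 costs ≈ 0.5 s per MFE fold and ≈ 3 s per partition function on
one core, so a 100-replicate jackknife at full length runs in about a
minute.

## Shotgun (3S) analysis

The 3S workflow compares a fragment probed in isolation with the
matching slice of the full-length profile (Pearson r, pairwise NO_DATA
deletion). Quantitative rules, which the original study describes only
qualitatively, are formalized here as:

- **independence threshold** `r ≥ 0.85` — splitting the observed gap
  between dependent (r ≤ 0.70) and independent (r ≥ 0.89) fragments;
  configurable;
- **crossing tolerance** 0.05 — a candidate model survives if, for every
  independent fragment, at most 5% of the pairs touching the fragment
  cross its boundary (terminal fraying pairs may cross); configurable;
- survivors ranked by energy; an empty survivor set is reported as
  "none consistent" rather than silently falling back.

A known limitation, reproduced by the generator: a fragment that bisects
helices whose strands happen to keep their pairing state in isolation can
still correlate above threshold (observed up to r ≈ 0.93 for worst-case
windows), in which case correlation-thresholded 3S can eliminate a true
model. Fragment panels should be domain-sized, as in the original
experiments.

## Jackknife confidence

For each of `n_reps = 100` replicates, `⌊0.10·n_defined⌋` of the
*measured* reactivities (removal applies only to positions that have
data) are masked to NO_DATA and the RNA refolded. A nucleotide agrees
when its partner — unpaired counting as partner "none" — equals the
reference model's; confidence is the agreement percentage. A relaxed
paired/unpaired-status mode is available (`match="status"`); partner
match is the default because it is the strictest interpretable choice.
With `drop_frac = 0` every replicate equals the reference refold and all
confidences are 100.

## Shannon entropy and well-defined regions

`S(i) = −Σ_{j≠i} P(i,j)·log₁₀ P(i,j)` over pairing partners only; the
unpaired mass is excluded and zero terms contribute zero. Base-10
logarithms are used because the customary 0.2 threshold for "low
entropy" is defined on that scale. Both tracks are median-smoothed with a
centered 51-nt window (edges replicated); maximal runs with smoothed
entropy ≤ 0.2 and smoothed confidence ≥ 70% of length ≥ 40 nt are
reported with means of the unsmoothed tracks.

## DMS validation

DMS reports single-stranded A/C only; G/U positions are NO_DATA by
construction. Classes: low < 0.4, high > 0.85, boundary values in the
middle class. "Helix termini" are the two terminal pairs of each maximal
stack (an isolated pair is its own terminus). The agreement statistic is
the percentage of highly reactive measured A/Cs that are unpaired or at a
terminus; with no highly reactive position the statistic is explicitly
undefined, not zero.

## Covariation

Candidate column pairs (a structure mapped through the reference row of a
Stockholm alignment) are scored with mutual information (log2) over the
joint base frequencies of sequences ungapped in both columns (pairwise
deletion, no gap symbol in the alphabet; fewer than 5 co-ungapped
sequences → undefined). The average product correction
`MIp = MI − mean_a·mean_b/grand_mean` is computed over the scored set.
Significance uses a permutation null — residues shuffled within each
column independently, gaps kept in place — with
`p = (1 + #{null ≥ observed})/(1 + n_perm)` on the MI statistic and
Benjamini–Hochberg FDR across the scored pairs. This is a transparent
analog of covariation tools like R-scape, not a reimplementation: its
null is not phylogeny-aware, and its significant set is not expected to
match R-scape's on real alignments.

Average percent identity is the mean over all sequence pairs of
identities over co-ungapped columns (conventions differ between tools;
this one is documented here because the number depends on it).

## Synthetic data generator

The generator defines the study conditions for every benchmark.

- **Ground truth.** A random sequence (GC fraction 0.5) is folded under a
  latent per-nucleotide pseudo-energy drawn once from `N(0, 0.8²)`
  kcal/mol — the scale of kT and of a single nucleotide's stacking
  share. The perturbation stands in for everything the nearest-neighbour
  model does not know about a real molecule, so the ground truth is a
  plausible low-energy structure that probing data, and not plain
  thermodynamics, can recover; without it, reactivity-free folding would
  trivially reproduce the truth and directed folding could show no gain.
  Structures with under 30% of nucleotides paired are resampled (bounded
  retries). `simulate_modular_rna` concatenates independently folded
  domains, giving a ground truth with no cross-domain pairs — the
  architecture 3S analysis is designed to detect.
- **Reactivities.** Paired sites draw from Gamma(shape 1.0, mean 0.12),
  unpaired from Gamma(shape 1.5, mean 0.90) — overlapping classes, so
  recovery is non-trivial; helix termini draw from the unpaired class
  with probability 0.5 (terminal pairs breathe); 5% dropout; DMS
  restricted to A/C; profiles are 2%/8%-normalized. Draws are keyed per
  (seed, absolute position, pairing state): chemical reactivity is a
  property of a site in the folded molecule, so a fragment position
  folded into the same state as in the full-length RNA reproduces the
  same value. This is what makes the experimentally observed
  fragment/full correlations of ~0.9+ for modular fragments possible at
  all — with i.i.d. per-measurement draws, replicate correlation would
  top out near 0.4 under these class distributions.
- **Fragments.** A fragment is refolded in isolation under the same
  latent field restricted to its window (the molecule does not change
  when truncated, only its context), then probed in absolute
  coordinates. Helper designers return the window with the fewest
  (modular) or most (worst-case) boundary-crossing pairs.
- **Ambiguous regions.** `suggest_ambiguous_region` places an 80-nt
  window where the data-directed ensemble has maximal mean Shannon
  entropy; `scramble_region` then replaces that window's data with
  fair-coin class draws. The region's fold hangs on conflicting
  evidence, which is the situation jackknife resampling is meant to
  flag. Simpler designs (coin data placed by bare-sequence entropy;
  uninformative crossover-reactivity values; concentrated missingness)
  were evaluated and rejected during design because thermodynamically
  pinned regions remain confident regardless of their data.
- **Homologs.** Ungapped alignments; background positions mutate
  independently at the given rate; each designed covarying pair is
  replaced, with probability twice the rate, by a random canonical pair
  — complementarity holds in every homolog by construction. Indels are
  not simulated; gap handling is tested with hand-built fixtures.

What passing these benchmarks shows: the inference machinery is exact
(oracle equivalence), and each statistic behaves as designed under data
whose generative process matches the method's assumptions. What it does
not show: performance on real probing data, whose noise is correlated
along the sequence, reagent- and pipeline-dependent, and not Gamma; nor
agreement with the original study's numbers, whose raw data and alignment
snapshot are not deposited and are treated as context, not targets.

## Problem sizes and seeds

Benchmarks use the study conditions where the workflow states them (100
jackknife replicates at 10% removal; 50-sequence alignments at background
rate 0.2 with 10 designed pairs; fragment panels over a 683-nt full
pipeline run) and package-chosen sizes elsewhere: 50 random sequences of
n ≤ 14 for oracle equivalence, 20 seeds at n = 300 for recovery and 3S,
10 seeds for jackknife/covariation/DMS cohorts, 400–1000 permutations for
the covariation null. All randomness flows from explicit integer seeds;
generators are pure functions of (parameters, seed) and repeat
byte-identically, as does the whole pipeline from its manifest.

## Known limitations

- The energy parameters are deliberately simplified; absolute energies
  and ensemble details differ from Turner-parameter engines, so numbers
  are comparable within this package, not across packages.
- No maximum pairing-distance option; very long-range pairs are allowed.
- The covariation module's FDR calibration is exact only under the
  within-column permutation null; phylogenetic correlation in real
  alignments inflates MI and is only partially absorbed by APC.
- The jackknife measures stability of the fold under data loss, not
  correctness; a stably wrong region scores high confidence.
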