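"""Synthetic probing data with known ground truth.

Every pipeline stage is testable without deposited data: this module draws
random sequences, fixes a thermodynamically plausible ground-truth
structure, and emulates SHAPE/DMS probing of it.

Ground truth.  A random sequence is folded under a latent per-nucleotide
stability perturbation (zero-mean Gaussian pseudo-energy, default sd
0.8 kcal/mol — the scale of kT and of a single nucleotide's stacking
contribution).  The perturbation stands in for everything the
nearest-neighbour model does not know about a real molecule (tertiary
contacts, ions, ligands), so the ground truth is a low-energy structure
that probing data — and not thermodynamics alone — can recover.

Reactivities.  Chemical reactivity is a property of a site in the folded
molecule, so each position carries latent paired- and unpaired-state
reactivity values drawn once per (seed, position, state) from the Gamma
mixture; the observed value is selected by the position's pairing state in
whatever structure is probed.  A fragment position folded into the same
state as in the full-length RNA therefore reproduces the same value —
without this, the high fragment/full correlations that define an
independent subdomain could not occur.  Dropout (NO_DATA) emulates
unmeasurable positions; DMS restricts data to A/C.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .conservation import StructuralAlignment
from .fold import (DEFAULT_MODEL, EnergyModel, PAIR_TYPES,
                   SecondaryStructure, fold_mfe)
from .profiles import ReactivityProfile, normalize_reactivities
from .shotgun import MIN_FRAGMENT_LENGTH, FragmentSpec

MIN_PERCENT_PAIRED = 30.0
MAX_RETRIES = 20


class SeedError(RuntimeError):
    """No sufficiently paired structure found within the retry bound."""


@dataclass(frozen=True)
class SimulationParams:
    """Probing-simulation settings.

    Paired positions draw from Gamma(shape 1.0, mean 0.12), unpaired from
    Gamma(shape 1.5, mean 0.90) — overlapping distributions, so recovery
    is non-trivial.  Helix-terminus positions draw from the unpaired
    distribution with probability 0.5 (terminal pairs breathe).
    """

    paired_shape: float = 1.0
    paired_mean: float = 0.12
    unpaired_shape: float = 1.5
    unpaired_mean: float = 0.90
    terminus_unpaired_prob: float = 0.5
    dropout: float = 0.05
    latent_sd: float = 0.8
    gc_fraction: float = 0.5
    point_mass: bool = False  # noise-free limit: paired -> 0, unpaired -> 1
    seed: int = 0

    def __post_init__(self):
        if not (self.paired_mean >= 0 and self.unpaired_mean > 0):
            raise ValueError("reactivity means must be positive")
        if self.paired_mean >= self.unpaired_mean:
            raise ValueError("paired mean must be below unpaired mean")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _rng(*keys) -> np.random.Generator:
    return np.random.default_rng(list(keys))


@dataclass
class SyntheticRNA:
    """A ground-truth bundle: sequence, structure and the latent field."""

    sequence: str
    structure: SecondaryStructure
    latent_dg: np.ndarray
    params: SimulationParams

    def __len__(self):
        return len(self.sequence)


def _latent_field(length: int, seed: int, attempt: int,
                  params: SimulationParams) -> np.ndarray:
    return _rng(seed, attempt, 7).normal(0.0, params.latent_sd, length)


def simulate_rna(length: int, seed: int,
                 params: SimulationParams | None = None,
                 model: EnergyModel = DEFAULT_MODEL) -> SyntheticRNA:
    """Random sequence plus its latent-perturbed MFE fold as ground truth.

    Resamples (bounded retries) until >= 30% of nucleotides are paired.
    Byte-reproducible for a given (seed, params).
    """
    if length < 30:
        raise ValueError("length must be >= 30")
    params = params or SimulationParams(seed=seed)
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for attempt in range(MAX_RETRIES):
        rng = _rng(seed, attempt, 11)
        sequence = "".join(rng.choice(list("ACGU"), size=length, p=probs))
        latent = _latent_field(length, seed, attempt, params)
        structure = fold_mfe(sequence, model=model, extra_stack_dg=latent)
        if 100.0 * (structure.partner >= 0).sum() / length >= MIN_PERCENT_PAIRED:
            return SyntheticRNA(sequence, structure, latent, params)
    raise SeedError(
        f"no structure with >= {MIN_PERCENT_PAIRED}% paired in "
        f"{MAX_RETRIES} attempts (seed {seed})")


def simulate_modular_rna(length: int, seed: int,
                         params: SimulationParams | None = None,
                         model: EnergyModel = DEFAULT_MODEL,
                         n_domains: int = 2) -> SyntheticRNA:
    """Ground truth built from independently folding domains.

    The sequence is a concatenation of ``n_domains`` stretches, each
    generated and folded in isolation (its own latent field), so the truth
    contains no cross-domain pairs — the architecture that shotgun (3S)
    fragment analysis is designed to detect.
    """
    if n_domains < 1:
        raise ValueError("need at least one domain")
    bounds = np.linspace(0, length, n_domains + 1).astype(int)
    seqs, partners, latents = [], [], []
    offset = 0
    for d in range(n_domains):
        sub = simulate_rna(int(bounds[d + 1] - bounds[d]), seed * 101 + d,
                           params, model)
        seqs.append(sub.sequence)
        p = sub.structure.partner.copy()
        p[p >= 0] += offset
        partners.append(p)
        latents.append(sub.latent_dg)
        offset += len(sub.sequence)
    sequence = "".join(seqs)
    structure = SecondaryStructure(sequence, np.concatenate(partners))
    return SyntheticRNA(sequence, structure, np.concatenate(latents),
                        params or SimulationParams(seed=seed))


def simulate_structure(length: int, seed: int,
                       params: SimulationParams | None = None,
                       model: EnergyModel = DEFAULT_MODEL
                       ) -> tuple[str, SecondaryStructure]:
    """(sequence, ground-truth structure); see :func:`simulate_rna`."""
    rna = simulate_rna(length, seed, params, model)
    return rna.sequence, rna.structure


def _site_value(params: SimulationParams, pos: int, unpaired: bool) -> float:
    """Latent reactivity of an absolute site in a given pairing state."""
    if params.point_mass:
        return 1.0 if unpaired else 0.0
    if unpaired:
        shape, mean = params.unpaired_shape, params.unpaired_mean
    else:
        shape, mean = params.paired_shape, params.paired_mean
        if mean <= 0:
            return 0.0
    return float(_rng(params.seed, pos, int(unpaired)).gamma(shape, mean / shape))


def simulate_reactivities(structure: SecondaryStructure,
                          reagent: str = "SHAPE",
                          params: SimulationParams | None = None,
                          offset: int = 1,
                          scramble_region: tuple[int, int] | None = None,
                          rna_id: str = "synthetic") -> ReactivityProfile:
    """Emulated, normalized probing profile for a structure.

    ``offset`` is the 1-based position of the structure's first nucleotide
    in the full-length coordinate system, so fragment profiles reuse the
    same per-site values.  ``scramble_region`` (1-based inclusive, absolute
    coordinates) makes a stretch uninformative: its pairing state is
    replaced by a fair coin, emulating a structurally ambiguous region.
    """
    params = params or SimulationParams()
    n = len(structure)
    from .dms import helix_terminus_positions

    termini = helix_terminus_positions(structure)
    values = np.empty(n)
    for k in range(n):
        pos = offset + k  # absolute coordinate keys the per-site draws
        unpaired = structure.partner[k] < 0
        if not unpaired and (k + 1) in termini:
            if _rng(params.seed, pos, 2).random() < params.terminus_unpaired_prob:
                unpaired = True
        if scramble_region and scramble_region[0] <= pos <= scramble_region[1]:
            unpaired = _rng(params.seed, pos, 4).random() < 0.5
        values[k] = _site_value(params, pos, unpaired)
    if params.dropout > 0:
        drop = _rng(params.seed, 3, offset, n).random(n) < params.dropout
        values[drop] = np.nan
    values = normalize_reactivities(values)
    return ReactivityProfile(rna_id=rna_id, sequence=structure.sequence,
                             reactivities=values, reagent=reagent,
                             offset=offset)


def simulate_fragment(rna: SyntheticRNA, spec: FragmentSpec,
                      params: SimulationParams | None = None,
                      model: EnergyModel = DEFAULT_MODEL,
                      reagent: str = "SHAPE") -> ReactivityProfile:
    """Probe a fragment folded in isolation.

    The fragment subsequence is refolded with the same latent stability
    field restricted to the fragment (the molecule does not change when
    truncated — only its context does), then reactivities are simulated
    from the fragment's own structure in absolute coordinates.  Modular
    fragments therefore correlate with the full-length profile while
    boundary-breaking fragments do not.
    """
    params = params or rna.params
    spec.check_within(len(rna))
    a, b = spec.start - 1, spec.end
    frag_structure = fold_mfe(rna.sequence[a:b], model=model,
                              extra_stack_dg=rna.latent_dg[a:b])
    return simulate_reactivities(frag_structure, reagent, params,
                                 offset=spec.start, rna_id=spec.name)


# ---------------------------------------------------------------------------
# region and fragment design helpers
# ---------------------------------------------------------------------------

AMBIGUOUS_WINDOW_LENGTH = 80


def suggest_ambiguous_region(sequence: str, profile: ReactivityProfile,
                             length: int = AMBIGUOUS_WINDOW_LENGTH,
                             model: EnergyModel = DEFAULT_MODEL
                             ) -> tuple[int, int]:
    """Place a designed ambiguous region (1-based inclusive window).

    The window of the given length with the highest mean Shannon entropy of
    the data-directed ensemble — i.e. where sequence plus probing data
    leave the structure least determined.  Replacing that window's data
    with coin draws (``scramble_region``) then yields a stretch whose fold
    hangs on conflicting evidence, the situation jackknife resampling is
    meant to flag.
    """
    from .confidence import shannon_entropy
    from .fold import partition_function

    ent = shannon_entropy(partition_function(sequence, profile, model)).entropy
    if length > len(ent):
        raise ValueError("window longer than the sequence")
    csum = np.concatenate([[0.0], np.cumsum(ent)])
    means = (csum[length:] - csum[:-length]) / length
    a = int(np.argmax(means))
    return (a + 1, a + length)

def _crossing_count(pairs, start, end):
    return sum(1 for i, j in pairs
               if (start <= i <= end) != (start <= j <= end))


def suggest_modular_fragment(structure: SecondaryStructure,
                             length: int | None = None,
                             name: str = "modular") -> FragmentSpec:
    """The window of the given length with the fewest boundary-crossing
    pairs in the ground truth (first window on ties)."""
    n = len(structure)
    L = length or max(MIN_FRAGMENT_LENGTH, int(round(0.4 * n)))
    pairs = structure.pair_list()
    best, best_start = None, 1
    for start in range(1, n - L + 2):
        c = _crossing_count(pairs, start, start + L - 1)
        if best is None or c < best:
            best, best_start = c, start
    return FragmentSpec(name, best_start, best_start + L - 1)


def suggest_disruptive_fragment(structure: SecondaryStructure,
                                length: int | None = None,
                                name: str = "disruptive") -> FragmentSpec:
    """The window of the given length that bisects the most base pairs —
    the worst-case fragment design (first window on ties)."""
    n = len(structure)
    L = length or max(MIN_FRAGMENT_LENGTH, int(round(0.4 * n)))
    pairs = structure.pair_list()
    if not pairs:
        raise ValueError("structure has no pairs to disrupt")
    best, best_start = -1, 1
    for start in range(1, n - L + 2):
        c = _crossing_count(pairs, start, start + L - 1)
        if c > best:
            best, best_start = c, start
    return FragmentSpec(name, best_start, best_start + L - 1)


# ---------------------------------------------------------------------------
# homolog alignments with designed covariation
# ---------------------------------------------------------------------------

def simulate_homologs(sequence: str, structure: SecondaryStructure,
                      n_seqs: int, background_rate: float,
                      covarying_pairs: list[tuple[int, int]],
                      seed: int = 0) -> StructuralAlignment:
    """Ungapped homolog alignment with compensatory variation.

    Non-covarying positions mutate independently at ``background_rate``;
    each designated pair is replaced, with probability
    ``2 * background_rate`` (a pair is two sites), by a random member of
    {AU, UA, GC, CG, GU, UG} — complementarity is preserved in every
    homolog by construction.  The reference sequence is the first row and
    the ground-truth structure becomes the SS_cons line.
    """
    if not 0 <= background_rate < 0.5:
        raise ValueError("background_rate must be in [0, 0.5)")
    pairset = set(structure.pair_list())
    for p in covarying_pairs:
        if p not in pairset:
            raise ValueError(f"covarying pair {p} not in the structure")
    cov_positions = {k for p in covarying_pairs for k in p}
    rng = _rng(seed, 13)
    bases = "ACGU"
    seqs = [sequence]
    ids = ["ref"]
    for h in range(1, n_seqs):
        s = list(sequence)
        for k in range(len(s)):
            pos = k + 1
            if pos in cov_positions:
                continue
            if rng.random() < background_rate:
                s[k] = rng.choice([b for b in bases if b != s[k]])
        for i, j in covarying_pairs:
            if rng.random() < 2 * background_rate:
                pair = PAIR_TYPES[rng.integers(0, 6)]
                s[i - 1], s[j - 1] = pair[0], pair[1]
        seqs.append("".join(s))
        ids.append(f"hom{h}")
    return StructuralAlignment(ids=ids, seqs=seqs, ref_id="ref",
                               ss_cons=structure.dot_bracket())
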