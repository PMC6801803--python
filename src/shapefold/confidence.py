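"""Per-nucleotide confidence and conformational entropy.

Jackknife resampling measures how stable each nucleotide's pairing is under
loss of probing data: a fraction of the measured reactivities is masked to
NO_DATA, the RNA is refolded, and a nucleotide scores an agreement when its
partner (or unpaired status) matches the reference model.  Shannon entropy
over the equilibrium pairing-partner distribution marks, independently of
resampling, how concentrated each nucleotide's base-pairing probability is;
regions that combine high confidence with low entropy (< 0.2 in log10
units) are well-defined structural domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .fold import (DEFAULT_MODEL, EnergyModel, PairProbabilityMatrix,
                   SecondaryStructure, fold_mfe)
from .profiles import ReactivityProfile

ENTROPY_MAX_DEFAULT = 0.2
CONFIDENCE_MIN_DEFAULT = 70.0
REGION_MIN_LENGTH = 40
SMOOTH_WINDOW = 51


@dataclass
class ConfidenceProfile:
    """Per-nucleotide jackknife confidence, percent in [0, 100]."""

    confidence: np.ndarray
    n_replicates: int
    drop_fraction: float
    seed: int

    def __post_init__(self):
        self.confidence = np.asarray(self.confidence, dtype=float)
        if ((self.confidence < 0) | (self.confidence > 100)).any():
            raise ValueError("confidence values must lie in [0, 100]")

    def __len__(self):
        return len(self.confidence)


@dataclass
class EntropyProfile:
    """Per-nucleotide Shannon entropy (log10 units, >= 0)."""

    entropy: np.ndarray

    def __post_init__(self):
        self.entropy = np.asarray(self.entropy, dtype=float)
        if (self.entropy < -1e-12).any():
            raise ValueError("entropy must be non-negative")
        self.entropy = np.maximum(self.entropy, 0.0)

    def __len__(self):
        return len(self.entropy)


def jackknife_confidence(sequence: str, profile: ReactivityProfile,
                         reference: SecondaryStructure,
                         model: EnergyModel = DEFAULT_MODEL,
                         n_reps: int = 100, drop_frac: float = 0.10,
                         seed: int = 0, match: str = "partner",
                         extra_stack_dg=None) -> ConfidenceProfile:
    """Mock-dataset refolding confidence per nucleotide.

    For each of ``n_reps`` replicates, a uniformly random
    ``floor(drop_frac * n_defined)``-subset of the *measured* reactivities
    is set to NO_DATA and the sequence refolded.  ``match='partner'``
    scores exact partner identity (unpaired counts as partner "none");
    ``match='status'`` relaxes to paired/unpaired agreement.  Reproducible
    for a given seed.
    """
    if not 0 <= drop_frac < 1:
        raise ValueError(f"drop_frac {drop_frac} outside [0, 1)")
    if match not in ("partner", "status"):
        raise ValueError(f"unknown match mode {match!r}")
    n = len(sequence)
    if len(reference) != n or len(profile) != n:
        raise ValueError("sequence, profile and reference lengths differ")
    rng = np.random.default_rng(seed)
    defined = np.flatnonzero(profile.defined_mask)
    n_drop = int(drop_frac * len(defined))
    ref_partner = reference.partner
    agree = np.zeros(n)
    for _ in range(n_reps):
        r = profile.reactivities.copy()
        if n_drop:
            r[rng.choice(defined, size=n_drop, replace=False)] = np.nan
        refold = fold_mfe(sequence, profile.with_reactivities(r), model,
                          extra_stack_dg=extra_stack_dg)
        if match == "partner":
            agree += refold.partner == ref_partner
        else:
            agree += (refold.partner >= 0) == (ref_partner >= 0)
    return ConfidenceProfile(100.0 * agree / n_reps, n_reps, drop_frac, seed)


def shannon_entropy(pmat: PairProbabilityMatrix) -> EntropyProfile:
    """S(i) = -sum_j P(i,j) * log10 P(i,j) over pairing partners.

    Zero-probability terms contribute 0; the unpaired mass is excluded
    (pairing-partner convention, under which the 0.2 threshold of the
    SHAPE-MaP literature applies).
    """
    pmat.validate()
    P = pmat.P
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log10(np.where(P > 0, P, 1.0)), 0.0)
    return EntropyProfile(terms.sum(axis=1))


def find_well_defined_regions(conf: ConfidenceProfile, ent: EntropyProfile,
                              conf_min: float = CONFIDENCE_MIN_DEFAULT,
                              ent_max: float = ENTROPY_MAX_DEFAULT,
                              min_len: int = REGION_MIN_LENGTH,
                              smooth_window: int = SMOOTH_WINDOW) -> list[dict]:
    """Maximal runs of smoothed low entropy AND high confidence.

    Both tracks are median-smoothed with a centered window (edge values
    replicated); maximal runs where smoothed entropy <= ent_max and
    smoothed confidence >= conf_min of length >= min_len are reported with
    1-based inclusive coordinates and means of the *unsmoothed* tracks.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    c = np.asarray(conf.confidence, dtype=float)
    e = np.asarray(ent.entropy, dtype=float)
    if len(c) != len(e):
        raise ValueError("confidence and entropy lengths differ")
    cs = median_filter(c, size=smooth_window, mode="nearest")
    es = median_filter(e, size=smooth_window, mode="nearest")
    ok = (es <= ent_max) & (cs >= conf_min)
    regions = []
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if j - i + 1 >= min_len:
            regions.append({
                "start": i + 1,
                "end": j + 1,
                "length": j - i + 1,
                "mean_confidence": float(c[i:j + 1].mean()),
                "mean_entropy": float(e[i:j + 1].mean()),
            })
        i = j + 1
    return regions


def confidence_entropy_table(sequence: str, profile: ReactivityProfile,
                             conf: ConfidenceProfile,
                             ent: EntropyProfile) -> pd.DataFrame:
    """Per-nucleotide CSV track: position, base, reactivity, confidence, entropy."""
    n = len(sequence)
    return pd.DataFrame({
        "position": np.arange(1, n + 1),
        "base": list(sequence),
        "reactivity": profile.reactivities,
        "confidence": conf.confidence,
        "entropy": ent.entropy,
    })
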