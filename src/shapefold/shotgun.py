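"""Shotgun secondary structure (3S) analysis.

Fragments of the full-length RNA are probed (here: simulated) in isolation.
A fragment whose reactivity profile correlates highly with the matching
region of the full-length profile folds the same way alone as in context —
it is an independent subdomain — and any candidate structure placing many
base pairs across that fragment's boundaries is inconsistent with the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fold import SecondaryStructure
from .profiles import ReactivityProfile, pearson_r

MIN_FRAGMENT_LENGTH = 50
#: fragment/full correlation at or above this calls an independent subdomain
INDEPENDENCE_THRESHOLD = 0.85
#: tolerated fraction of boundary-crossing pairs (terminal fraying)
CROSSING_TOLERANCE = 0.05


@dataclass(frozen=True)
class FragmentSpec:
    """Named 1-based inclusive subinterval of the full-length RNA."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start < self.end:
            raise ValueError(f"{self.name}: need 1 <= start < end")
        if len(self) < MIN_FRAGMENT_LENGTH:
            raise ValueError(
                f"{self.name}: fragment shorter than {MIN_FRAGMENT_LENGTH} nt")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def check_within(self, n: int):
        if self.end > n:
            raise ValueError(f"{self.name}: end {self.end} beyond length {n}")


def fragment_correlation(full: ReactivityProfile, frag: ReactivityProfile,
                         spec: FragmentSpec) -> dict:
    """Pearson r between a fragment profile and the full-length slice."""
    spec.check_within(full.offset + len(full) - 1)
    if len(frag) != len(spec):
        raise ValueError(
            f"{spec.name}: fragment profile length {len(frag)} != "
            f"spec length {len(spec)}")
    piece = full.slice(spec.start, spec.end)
    r, n_used = pearson_r(piece.reactivities, frag.reactivities)
    return {"r": r, "n_used": n_used}


def is_independent_subdomain(r: float,
                             threshold: float = INDEPENDENCE_THRESHOLD) -> bool:
    """r >= threshold (boundary inclusive)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return r >= threshold


def external_pair_fraction(structure: SecondaryStructure,
                           spec: FragmentSpec) -> float:
    """Fraction of region-touching pairs that cross the region boundary."""
    spec.check_within(len(structure))
    crossing = touching = 0
    for i, j in structure.pair_list():
        inside_i = spec.start <= i <= spec.end
        inside_j = spec.start <= j <= spec.end
        if inside_i or inside_j:
            touching += 1
            if inside_i != inside_j:
                crossing += 1
    return crossing / touching if touching else 0.0


def select_model(candidates: list[SecondaryStructure],
                 fragments: list[tuple[FragmentSpec, float]],
                 threshold: float = INDEPENDENCE_THRESHOLD,
                 tolerance: float = CROSSING_TOLERANCE) -> dict:
    """Eliminate candidates that break independent-fragment boundaries.

    A candidate survives iff for every fragment classified independent
    (r >= threshold) its external-pair fraction is <= tolerance.  Survivors
    are ranked by energy (ascending, unscored structures last).  When no
    candidate is consistent, all are returned flagged ``none_consistent``
    rather than silently falling back.

    Returns ``{"survivors", "ranked", "diagnostics", "none_consistent"}``
    with per-candidate, per-fragment crossing counts in ``diagnostics``.
    """
    if not candidates:
        raise ValueError("no candidate structures")
    independent = [(spec, r) for spec, r in fragments
                   if is_independent_subdomain(r, threshold)]
    rows = []
    consistent = []
    for idx, cand in enumerate(candidates):
        ok = True
        for spec, r in fragments:
            frac = external_pair_fraction(cand, spec)
            crossing = sum(1 for i, j in cand.pair_list()
                           if (spec.start <= i <= spec.end)
                           != (spec.start <= j <= spec.end))
            indep = is_independent_subdomain(r, threshold)
            rows.append({
                "model": idx,
                "energy": cand.energy,
                "fragment": spec.name,
                "r": r,
                "independent": indep,
                "crossing_pairs": crossing,
                "external_fraction": frac,
            })
            if indep and frac > tolerance:
                ok = False
        if ok:
            consistent.append(idx)
    none_consistent = not consistent
    pool = list(range(len(candidates))) if none_consistent else consistent

    def rank_key(idx):
        e = candidates[idx].energy
        return (e is None, e if e is not None else 0.0, idx)

    ranked = sorted(pool, key=rank_key)
    return {
        "survivors": [candidates[i] for i in ranked],
        "ranked": ranked,
        "diagnostics": pd.DataFrame(rows),
        "none_consistent": none_consistent,
    }


def fragment_specs_from_csv(path) -> list[FragmentSpec]:
    """Read "name,start,end" rows (header optional)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if cols != ["name", "start", "end"]:
        df = pd.read_csv(path, header=None, names=["name", "start", "end"])
    return [FragmentSpec(str(r["name"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]
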