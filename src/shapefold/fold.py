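"""SHAPE-directed thermodynamic folding.

The engine is a nearest-neighbour dynamic program over nested secondary
structures: minimum free energy with deterministic traceback, complete
suboptimal generation within an energy window (Wuchty-style, best-first),
and the McCaskill partition function with equilibrium base-pair
probabilities.  Probing data enter as Deigan-style pseudo-free energies
``dG(i) = m * ln(r_i + 1) + b`` added per stacked nucleotide.

The bundled energy parameters are a simplified Turner-like set: stacking
energies additive in the strengths of the two pairs, loop-length penalties
tabulated and extrapolated with the Jacobson-Stockmayer term
``1.75 * RT * ln(n/n0)``, and a linear multibranch penalty.  The model is
pluggable — any :class:`EnergyModel` with the same table shapes can be
substituted.  Pseudoknots, coaxial stacking and dangling ends are outside
the model; lonely pairs are allowed.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .profiles import ReactivityProfile, clean_sequence

UNPAIRED = -1
_BASES = "ACGU"
_BASE_INDEX = {b: k for k, b in enumerate(_BASES)}
#: canonical pair types, order CG GC GU UG AU UA
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PT = np.full((4, 4), -1, dtype=np.int8)
for _k, _p in enumerate(PAIR_TYPES):
    _PT[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = _k

GAS_CONSTANT = 0.0019872  # kcal/(mol*K)


class InvariantViolation(ValueError):
    """A SecondaryStructure breaks a structural invariant."""


def encode(sequence: str) -> np.ndarray:
    seq = clean_sequence(sequence)
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

def _default_stack() -> np.ndarray:
    # additive in pair strengths => symmetric under strand reversal
    strength = np.array([1.5, 1.5, 0.45, 0.45, 0.9, 0.9])
    return -(strength[:, None] + strength[None, :])


@dataclass
class EnergyModel:
    """Nearest-neighbour parameters plus the SHAPE pseudo-energy line.

    ``stack`` is a 6x6 table over :data:`PAIR_TYPES` (outer pair x inner
    pair, kcal/mol).  Loop initiation penalties are tabulated up to
    ``loop_tab_max`` unpaired nucleotides and extended by the
    Jacobson-Stockmayer term beyond.  ``shape_m``/``shape_b`` are the
    pseudo-energy slope and intercept (kcal/mol) applied per stacked
    nucleotide.
    """

    stack: np.ndarray = field(default_factory=_default_stack)
    hairpin_init: float = 5.4     # loop of 3
    bulge_init: float = 3.8       # loop of 1
    internal_init: float = 1.7    # loop of 2
    loop_tab_max: int = 30
    ninio_m: float = 0.5
    ninio_max: float = 3.0
    ml_a: float = 3.4             # multibranch offset
    ml_b: float = 0.4             # per branch (closing pair included)
    ml_c: float = 0.0             # per unpaired nucleotide
    temperature: float = 310.15   # kelvin
    shape_m: float = 2.6
    shape_b: float = -0.8

    def __post_init__(self):
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.shape != (6, 6):
            raise ValueError("stack table must be 6x6")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        flip = [1, 0, 3, 2, 5, 4]
        if not np.allclose(self.stack, self.stack[np.ix_(flip, flip)].T):
            raise ValueError("stack table not symmetric under strand reversal")
        self._tab_cache: dict[int, tuple] = {}

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    def loop_tables(self, n: int):
        """(hairpin, bulge, internal) penalty arrays indexed by loop size."""
        size = max(n, self.loop_tab_max) + 1
        if size in self._tab_cache:
            return self._tab_cache[size]
        js = 1.75 * self.RT
        idx = np.arange(size, dtype=float)
        with np.errstate(divide="ignore"):
            hairpin = self.hairpin_init + js * np.log(np.maximum(idx, 3) / 3.0)
            bulge = self.bulge_init + js * np.log(np.maximum(idx, 1) / 1.0)
            internal = self.internal_init + js * np.log(np.maximum(idx, 2) / 2.0)
        hairpin[:3] = _dp.INF  # hairpin loops need >= 3 unpaired
        bulge[0] = _dp.INF
        internal[:2] = _dp.INF
        tabs = (hairpin, bulge, internal)
        self._tab_cache[size] = tabs
        return tabs


DEFAULT_MODEL = EnergyModel()


def pseudo_energy(reactivity: float, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Deigan pseudo-free energy for one nucleotide; NO_DATA -> 0."""
    if reactivity is None or (isinstance(reactivity, float) and math.isnan(reactivity)):
        return 0.0
    if reactivity < 0:
        raise ValueError(f"negative reactivity {reactivity}")
    return model.shape_m * math.log(reactivity + 1.0) + model.shape_b


def pseudo_energy_vector(profile, n: int, model: EnergyModel) -> np.ndarray:
    """Per-nucleotide pseudo-energy vector (zeros without a profile)."""
    dg = np.zeros(n)
    if profile is None:
        return dg
    r = np.asarray(profile.reactivities if isinstance(profile, ReactivityProfile)
                   else profile, dtype=float)
    if len(r) != n:
        raise ValueError(f"profile length {len(r)} != sequence length {n}")
    ok = ~np.isnan(r)
    dg[ok] = model.shape_m * np.log(r[ok] + 1.0) + model.shape_b
    return dg


# ---------------------------------------------------------------------------
# secondary structure container
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """Nested base-pair table for one sequence.

    ``partner`` is 0-based internally: ``partner[i] = j`` or -1.  The
    public accessors (:meth:`pair_list`, :meth:`partner_of`) speak 1-based
    coordinates, matching the rest of the package.
    """

    sequence: str
    partner: np.ndarray
    energy: float | None = None

    def __post_init__(self):
        self.sequence = clean_sequence(self.sequence)
        self.partner = np.asarray(self.partner, dtype=np.int64).copy()
        if len(self.partner) != len(self.sequence):
            raise InvariantViolation("partner table length != sequence length")
        self.validate()

    def validate(self):
        n = len(self.sequence)
        seq = self.sequence
        stack = []
        for i in range(n):
            j = int(self.partner[i])
            if j == UNPAIRED:
                continue
            if not 0 <= j < n or j == i:
                raise InvariantViolation(f"partner[{i}] = {j} out of range")
            if self.partner[j] != i:
                raise InvariantViolation(f"pair ({i+1},{j+1}) not involutive")
            if j > i:
                if j - i < 4:
                    raise InvariantViolation(
                        f"hairpin loop of pair ({i+1},{j+1}) shorter than 3")
                if _PT[_BASE_INDEX[seq[i]], _BASE_INDEX[seq[j]]] < 0:
                    raise InvariantViolation(
                        f"non-canonical pair {seq[i]}{seq[j]} at ({i+1},{j+1})")
                if stack and j > stack[-1]:
                    raise InvariantViolation(
                        f"pseudoknot: pair ({i+1},{j+1}) crosses ({stack[-1]+1})")
                stack.append(j)
            else:
                if not stack or stack[-1] != i:
                    raise InvariantViolation(f"crossing pair at {i+1}")
                stack.pop()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return int((self.partner >= 0).sum()) // 2

    def pair_list(self) -> list[tuple[int, int]]:
        """Sorted 1-based (i, j) pairs with i < j."""
        return [(i + 1, int(j) + 1) for i, j in enumerate(self.partner)
                if j > i]

    def partner_of(self, pos: int) -> int:
        """1-based partner of 1-based ``pos`` (0 if unpaired)."""
        j = int(self.partner[pos - 1])
        return j + 1 if j >= 0 else 0

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)

    @classmethod
    def from_dot_bracket(cls, sequence: str, db: str,
                         energy: float | None = None) -> "SecondaryStructure":
        if len(sequence) != len(db):
            raise ValueError("sequence and dot-bracket lengths differ")
        partner = np.full(len(db), UNPAIRED, dtype=np.int64)
        stack = []
        for i, c in enumerate(db):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i+1}")
                j = stack.pop()
                partner[j] = i
                partner[i] = j
            elif c != ".":
                raise ValueError(f"illegal dot-bracket symbol {c!r}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]+1}")
        return cls(sequence, partner, energy)

    def helices(self) -> list[list[tuple[int, int]]]:
        """Maximal stacks of consecutive pairs, 1-based, 5'->3' order."""
        pairs = self.pair_list()
        pairset = set(pairs)
        helices = []
        for i, j in pairs:
            if (i - 1, j + 1) in pairset:
                continue  # not the outermost pair of its stack
            run = [(i, j)]
            while (run[-1][0] + 1, run[-1][1] - 1) in pairset:
                run.append((run[-1][0] + 1, run[-1][1] - 1))
            helices.append(run)
        return helices


# ---------------------------------------------------------------------------
# CT and dot-bracket files
# ---------------------------------------------------------------------------

def write_ct(structure: SecondaryStructure, path):
    n = len(structure)
    e = structure.energy
    header = f"{n}\tENERGY = {e:.2f}" if e is not None else f"{n}\tstructure"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n):
            j = int(structure.partner[i])
            fh.write(f"{i+1}\t{structure.sequence[i]}\t{i}\t{i+2}\t"
                     f"{j+1 if j >= 0 else 0}\t{i+1}\n")


def read_ct(path) -> SecondaryStructure:
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        energy = None
        for tok_prev, tok in zip(header, header[1:]):
            if tok_prev == "=":
                energy = float(tok)
        seq = []
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for _ in range(n):
            parts = fh.readline().split()
            idx = int(parts[0]) - 1
            seq.append(parts[1])
            p = int(parts[4])
            partner[idx] = p - 1 if p > 0 else UNPAIRED
    return SecondaryStructure("".join(seq), partner, energy)


def write_dot_bracket(structure: SecondaryStructure, path, name: str = "structure"):
    with open(path, "w") as fh:
        fh.write(f">{name}\n{structure.sequence}\n{structure.dot_bracket()}\n")


def read_dot_bracket(path) -> SecondaryStructure:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ValueError("dot-bracket file needs sequence and structure lines")
    return SecondaryStructure.from_dot_bracket(lines[0], lines[1])


# ---------------------------------------------------------------------------
# folding entry points
# ---------------------------------------------------------------------------

def _prepare(sequence: str, profile, model: EnergyModel, extra_stack_dg=None):
    seq_idx = encode(sequence)
    n = len(seq_idx)
    pt = _PT[seq_idx[:, None], seq_idx[None, :]]
    dg = pseudo_energy_vector(profile, n, model)
    if extra_stack_dg is not None:
        extra = np.asarray(extra_stack_dg, dtype=float)
        if len(extra) != n:
            raise ValueError("extra_stack_dg length mismatch")
        dg = dg + extra
    hairpin, bulge, internal = model.loop_tables(n)
    return seq_idx, pt, dg, hairpin, bulge, internal


def _fill(sequence, profile, model, extra_stack_dg=None):
    seq_idx, pt, dg, hp, bu, il = _prepare(sequence, profile, model,
                                           extra_stack_dg)
    V, M, M1, W = _dp.fill_mfe(pt, dg, model.stack, hp, bu, il,
                               model.ninio_m, model.ninio_max,
                               model.ml_a, model.ml_b)
    return seq_idx, pt, dg, hp, bu, il, V, M, M1, W


def fold_mfe(sequence: str, profile=None, model: EnergyModel = DEFAULT_MODEL,
             extra_stack_dg=None) -> SecondaryStructure:
    """Minimum-free-energy structure under the model plus pseudo-energies.

    Traceback is deterministic: on ties, unpaired is preferred, then the
    first candidate in a fixed scan order, so repeated calls are
    bit-reproducible.
    """
    seq_idx, pt, dg, hp, bu, il, V, M, M1, W = _fill(sequence, profile, model,
                                                     extra_stack_dg)
    partner = _dp.traceback_mfe(pt, dg, model.stack, hp, bu, il,
                                model.ninio_m, model.ninio_max,
                                model.ml_a, model.ml_b, V, M, M1, W)
    n = len(seq_idx)
    return SecondaryStructure(sequence, partner, float(W[n]) if n else 0.0)


def energy_of(structure: SecondaryStructure, profile=None,
              model: EnergyModel = DEFAULT_MODEL,
              extra_stack_dg=None) -> float:
    """Score a structure by explicit loop decomposition.

    Independent of the DP fill: the structure is decomposed into hairpin,
    stack, bulge/internal and multibranch loops, each scored from the model
    tables.  Used both for re-scoring and as part of the enumeration oracle.
    """
    seq_idx, pt, dg, hp, bu, il = _prepare(structure.sequence, profile, model,
                                           extra_stack_dg)
    partner = structure.partner
    total = 0.0

    def score_closed(i: int, j: int) -> float:
        children = []
        k = i + 1
        while k < j:
            if partner[k] >= 0:
                children.append((k, int(partner[k])))
                k = int(partner[k]) + 1
            else:
                k += 1
        if not children:
            return float(hp[j - i - 1])
        if len(children) == 1:
            (k, l), = children
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                e = (model.stack[pt[i, j], pt[k, l]]
                     + dg[i] + dg[j] + dg[k] + dg[l])
            elif u1 == 0 or u2 == 0:
                e = float(bu[u1 + u2])
            else:
                e = float(il[u1 + u2]) + min(model.ninio_max,
                                             model.ninio_m * abs(u1 - u2))
            return e + score_closed(k, l)
        e = model.ml_a + model.ml_b * (1 + len(children))
        e += model.ml_c * ((j - i - 1) - sum(l - k + 1 for k, l in children))
        return e + sum(score_closed(k, l) for k, l in children)

    i = 0
    n = len(partner)
    while i < n:
        if partner[i] > i:
            total += score_closed(i, int(partner[i]))
            i = int(partner[i]) + 1
        else:
            i += 1
    return total


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (small n)
# ---------------------------------------------------------------------------

ENUMERATION_MAX_N = 20


def enumerate_structures(sequence: str, model: EnergyModel = DEFAULT_MODEL,
                         profile=None, extra_stack_dg=None
                         ) -> list[SecondaryStructure]:
    """All nested structures with their energies (n <= 20 guard).

    Generation is independent of the DP: pair sets are built by direct
    recursion over the leftmost position, then scored with
    :func:`energy_of`.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    if n > ENUMERATION_MAX_N:
        raise ValueError(f"enumeration refused for n = {n} > {ENUMERATION_MAX_N}")
    seq_idx = encode(seq)
    pt = _PT[seq_idx[:, None], seq_idx[None, :]]
    memo: dict[tuple[int, int], list[tuple]] = {}

    def region(i: int, j: int) -> list[tuple]:
        if j - i < 4:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(region(i + 1, j))
        for l in range(i + 4, j + 1):
            if pt[i, l] < 0:
                continue
            for inner in region(i + 1, l - 1):
                for rest in region(l + 1, j):
                    out.append(((i, l),) + inner + rest)
        memo[key] = out
        return out

    structures = []
    for pairs in region(0, n - 1):
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for i, j in pairs:
            partner[i] = j
            partner[j] = i
        s = SecondaryStructure(seq, partner)
        s.energy = energy_of(s, profile, model, extra_stack_dg)
        structures.append(s)
    structures.sort(key=lambda s: (s.energy, s.dot_bracket()))
    return structures


# ---------------------------------------------------------------------------
# Wuchty-style complete suboptimal generation (best-first)
# ---------------------------------------------------------------------------

_EXT, _V, _M, _M1 = 0, 1, 2, 3


def fold_suboptimal(sequence: str, profile=None,
                    model: EnergyModel = DEFAULT_MODEL, max_models: int = 20,
                    window: float | None = None, extra_stack_dg=None
                    ) -> list[SecondaryStructure]:
    """Distinct structures with energy <= MFE + window, energy-sorted.

    Best-first expansion over the filled matrices emits structures in
    non-decreasing energy order (the priority of a partial state is the
    exact minimum energy of its completions), truncated to ``max_models``.
    ``window`` defaults to 20% of \\|MFE\\|.
    """
    if max_models < 1:
        raise ValueError("max_models must be >= 1")
    seq_idx, pt, dg, hp, bu, il, V, M, M1, W = _fill(sequence, profile, model,
                                                     extra_stack_dg)
    n = len(seq_idx)
    mfe = float(W[n]) if n else 0.0
    if window is None:
        window = 0.2 * abs(mfe)
    if window < 0:
        raise ValueError("window must be >= 0")
    limit = mfe + window + 1e-9
    INF = _dp.INF
    ml_a, ml_b = model.ml_a, model.ml_b

    def val(kind, i, j):
        if kind == _EXT:
            return W[j + 1]  # j may be -1
        if kind == _V:
            return V[i, j]
        if kind == _M:
            return M[i, j]
        return M1[i, j]

    def interior_e(i, j, k, l):
        u1, u2 = k - i - 1, j - l - 1
        if u1 == 0 and u2 == 0:
            return (model.stack[pt[i, j], pt[k, l]]
                    + dg[i] + dg[j] + dg[k] + dg[l])
        if u1 == 0 or u2 == 0:
            return bu[u1 + u2]
        return il[u1 + u2] + min(model.ninio_max, model.ninio_m * abs(u1 - u2))

    # state: (bound, tiebreak, intervals cons-list, pairs cons-list)
    counter = itertools.count()
    heap = []
    if n:
        start = (mfe, -next(counter), ((_EXT, 0, n - 1), None), None)
        heapq.heappush(heap, start)
    else:
        heap = []
    results: list[SecondaryStructure] = []
    seen: set[frozenset] = set()

    def push(bound, intervals, pairs):
        if bound <= limit:
            heapq.heappush(heap, (bound, -next(counter), intervals, pairs))

    while heap and len(results) < max_models:
        bound, _, intervals, pairs = heapq.heappop(heap)
        if bound > limit:
            break
        if intervals is None:
            plist = []
            node = pairs
            while node is not None:
                plist.append(node[0])
                node = node[1]
            key = frozenset(plist)
            if key in seen:
                continue
            seen.add(key)
            partner = np.full(n, UNPAIRED, dtype=np.int64)
            for i, j in plist:
                partner[i] = j
                partner[j] = i
            s = SecondaryStructure(sequence, partner)
            s.energy = energy_of(s, profile, model, extra_stack_dg)
            results.append(s)
            continue
        (kind, i, j), rest = intervals
        base = bound - val(kind, i, j)
        if kind == _EXT:
            if j < 0:
                push(bound, rest, pairs)
                continue
            # j unpaired
            push(base + W[j], ((_EXT, 0, j - 1), rest), pairs)
            for k in range(0, j - 3):
                if V[k, j] >= INF:
                    continue
                b2 = base + W[k] + V[k, j]
                if b2 > limit:
                    continue
                iv = ((_V, k, j), ((_EXT, 0, k - 1), rest))
                push(b2, iv, ((k, j), pairs))
        elif kind == _V:
            if hp[j - i - 1] < INF:
                push(base + hp[j - i - 1], rest, pairs)
            kmax = min(i + _dp.MAXLOOP + 1, j - 5)
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                lmin = max(k + 4, j - 1 - (_dp.MAXLOOP - u1))
                for l in range(j - 1, lmin - 1, -1):
                    if pt[k, l] < 0 or V[k, l] >= INF:
                        continue
                    b2 = base + interior_e(i, j, k, l) + V[k, l]
                    if b2 > limit:
                        continue
                    push(b2, ((_V, k, l), rest), ((k, l), pairs))
            for k in range(i + 2, j - 4):
                if M[i + 1, k - 1] >= INF or M1[k, j - 1] >= INF:
                    continue
                b2 = base + ml_a + ml_b + M[i + 1, k - 1] + M1[k, j - 1]
                if b2 > limit:
                    continue
                iv = ((_M, i + 1, k - 1), ((_M1, k, j - 1), rest))
                push(b2, iv, pairs)
        elif kind == _M:
            for k in range(i, j + 1):
                if M1[k, j] >= INF:
                    continue
                push(base + M1[k, j], ((_M1, k, j), rest), pairs)
                if k > i and M[i, k - 1] < INF:
                    b2 = base + M[i, k - 1] + M1[k, j]
                    if b2 <= limit:
                        iv = ((_M, i, k - 1), ((_M1, k, j), rest))
                        push(b2, iv, pairs)
        else:  # _M1
            if j - 1 >= i + 4 and M1[i, j - 1] < INF:
                push(base + M1[i, j - 1], ((_M1, i, j - 1), rest), pairs)
            if pt[i, j] >= 0 and V[i, j] < INF:
                b2 = base + ml_b + V[i, j]
                if b2 <= limit:
                    push(b2, ((_V, i, j), rest), ((i, j), pairs))

    if not results and n:
        # window excluded everything but the MFE path was prunable only by
        # numerical noise; fall back to the deterministic MFE structure
        results = [fold_mfe(sequence, profile, model, extra_stack_dg)]
    results.sort(key=lambda s: s.energy)
    return results


# ---------------------------------------------------------------------------
# partition function and pair probabilities
# ---------------------------------------------------------------------------

@dataclass
class PairProbabilityMatrix:
    """Equilibrium base-pair probabilities.

    ``P`` is symmetric, ``P[i, j]`` = probability (0-based) that i pairs
    with j.  ``prob(i, j)`` and :meth:`unpaired_probability` speak the
    package's 1-based coordinates.
    """

    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def prob(self, i: int, j: int) -> float:
        return float(self.P[i - 1, j - 1])

    def paired_probability(self) -> np.ndarray:
        return self.P.sum(axis=1)

    def unpaired_probability(self) -> np.ndarray:
        return 1.0 - self.paired_probability()

    def validate(self):
        if (self.P < -1e-9).any() or (self.P > 1 + 1e-9).any():
            raise InvariantViolation("pair probability outside [0, 1]")
        if (self.P.sum(axis=1) > 1 + 1e-9).any():
            raise InvariantViolation("total pairing probability exceeds 1")


def partition_function(sequence: str, profile=None,
                       model: EnergyModel = DEFAULT_MODEL,
                       extra_stack_dg=None) -> PairProbabilityMatrix:
    """McCaskill partition function over the same energy rules as the MFE.

    Boltzmann factors are rescaled per nucleotide by ``exp(-MFE/(n*RT))``
    so the recursion stays finite for n up to a few thousand.
    """
    seq_idx, pt, dg, hp, bu, il, V, M, M1, W = _fill(sequence, profile, model,
                                                     extra_stack_dg)
    n = len(seq_idx)
    if n == 0:
        return PairProbabilityMatrix(np.zeros((0, 0)))
    RT = model.RT
    mfe = float(W[n])
    s = math.exp(-mfe / (RT * n)) if mfe < 0 else 1.0
    spow = np.power(s, -np.arange(n + 3, dtype=float))
    Qb, QM, QM1, Qf, Qbk = _dp.fill_partition(
        pt, dg, model.stack, hp, bu, il, model.ninio_m, model.ninio_max,
        model.ml_a, model.ml_b, RT, spow)
    P = _dp.pair_probabilities(
        pt, dg, model.stack, hp, bu, il, model.ninio_m, model.ninio_max,
        model.ml_a, model.ml_b, RT, spow, Qb, QM, QM1, Qf, Qbk)
    P = P + P.T
    mat = PairProbabilityMatrix(P)
    mat.validate()
    return mat


# ---------------------------------------------------------------------------
# structural element accounting
# ---------------------------------------------------------------------------

def structure_stats(structure: SecondaryStructure) -> dict:
    """Element counts: percent paired, helices, loops, junction degrees.

    A helix is a maximal stack of consecutive pairs; an internal loop is
    the region between two helices with unpaired nucleotides on one or both
    strands (asymmetric when the two side lengths differ, bulges included);
    a terminal loop is a hairpin loop; a junction's degree is the number of
    helices meeting at a multibranch loop (closing helix included).
    """
    structure.validate()
    partner = structure.partner
    n = len(partner)
    n_paired = int((partner >= 0).sum())
    stats = {
        "percent_paired": 100.0 * n_paired / n if n else 0.0,
        "n_helices": len(structure.helices()),
        "n_internal_loops": 0,
        "n_asymmetric": 0,
        "n_terminal_loops": 0,
        "junctions": {},
    }

    def walk(i: int, j: int):
        children = []
        k = i + 1
        while k < j:
            if partner[k] >= 0:
                children.append((k, int(partner[k])))
                k = int(partner[k]) + 1
            else:
                k += 1
        if not children:
            stats["n_terminal_loops"] += 1
        elif len(children) == 1:
            (k, l), = children
            u1, u2 = k - i - 1, j - l - 1
            if u1 + u2 > 0:
                stats["n_internal_loops"] += 1
                if u1 != u2:
                    stats["n_asymmetric"] += 1
        else:
            deg = len(children) + 1
            stats["junctions"][deg] = stats["junctions"].get(deg, 0) + 1
        for k, l in children:
            walk(k, l)

    i = 0
    while i < n:
        if partner[i] > i:
            walk(i, int(partner[i]))
            i = int(partner[i]) + 1
        else:
            i += 1
    return stats
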