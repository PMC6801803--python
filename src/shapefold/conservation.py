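"""Alignment-based conservation and covariation screening.

Conserved base pairing leaves a covariation signature: the two columns of a
true pair mutate jointly so that complementarity is preserved.  This module
scores candidate column pairs with mutual information (log2), applies the
average product correction (APC) to strip shared phylogenetic background,
and calibrates significance with a within-column permutation null plus
Benjamini-Hochberg FDR.  It is a transparent analog of covariation tools
like R-scape, not a reimplementation — its significant set answers the
same question (are paired columns covarying beyond chance?) with fully
auditable computation.

Alignments travel as Stockholm 1.0 with a ``#=GC SS_cons`` consensus
structure line (WUSS brackets; pseudoknot letters are ignored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from statsmodels.stats.multitest import multipletests

from .fold import SecondaryStructure

GAP_CHARS = "-.~"
_OPEN = "(<[{"
_CLOSE = ")>]}"
MIN_SEQS_FOR_COVARIATION = 5
MIN_COUNGAPPED = 5


class AlignmentFormatError(ValueError):
    pass


def _clean_aligned(seq: str) -> str:
    out = []
    for c in seq.upper().replace("T", "U"):
        out.append("-" if c in GAP_CHARS else c)
    return "".join(out)


def parse_ss_cons(ss: str) -> list[tuple[int, int]]:
    """Column pairs (1-based) from a WUSS/dot-bracket consensus line."""
    stacks: dict[str, list[int]] = {o: [] for o in _OPEN}
    pairs = []
    for col, c in enumerate(ss, 1):
        if c in _OPEN:
            stacks[c].append(col)
        elif c in _CLOSE:
            o = _OPEN[_CLOSE.index(c)]
            if not stacks[o]:
                raise AlignmentFormatError(
                    f"unbalanced {c!r} at SS_cons column {col}")
            pairs.append((stacks[o].pop(), col))
    for o, st in stacks.items():
        if st:
            raise AlignmentFormatError(
                f"unbalanced {o!r} at SS_cons column {st[-1]}")
    return sorted(pairs)


@dataclass
class StructuralAlignment:
    """Multiple alignment plus a consensus pair list.

    Sequences are stored aligned (gap '-', uppercase, U-normalized).  The
    first sequence is the reference unless ``ref_id`` names another row.
    """

    ids: list[str]
    seqs: list[str]
    ref_id: str = ""
    ss_cons: str | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.seqs) or not self.ids:
            raise AlignmentFormatError("ids and sequences mismatch or empty")
        self.seqs = [_clean_aligned(s) for s in self.seqs]
        ncol = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != ncol:
                raise AlignmentFormatError(f"ragged row {sid!r}")
        if not self.ref_id:
            self.ref_id = self.ids[0]
        if self.ref_id not in self.ids:
            raise AlignmentFormatError(f"reference {self.ref_id!r} not in alignment")
        if self.ss_cons is not None and len(self.ss_cons) != ncol:
            raise AlignmentFormatError("SS_cons length != alignment length")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def ref_seq_aligned(self) -> str:
        return self.seqs[self.ids.index(self.ref_id)]

    @property
    def ref_seq(self) -> str:
        return self.ref_seq_aligned.replace("-", "")

    def column_pairs(self) -> list[tuple[int, int]]:
        if self.ss_cons is None:
            raise AlignmentFormatError("alignment carries no SS_cons line")
        return parse_ss_cons(self.ss_cons)

    def ref_to_col(self) -> dict[int, int]:
        """1-based reference position -> 1-based alignment column."""
        out = {}
        pos = 0
        for col, c in enumerate(self.ref_seq_aligned, 1):
            if c != "-":
                pos += 1
                out[pos] = col
        return out

    def col_to_ref(self) -> dict[int, int]:
        return {c: p for p, c in self.ref_to_col().items()}


def read_stockholm(path) -> StructuralAlignment:
    """Read Stockholm 1.0; ``#=GC SS_cons`` becomes the consensus pairs."""
    aln = AlignIO.read(path, "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    return StructuralAlignment(
        ids=[rec.id for rec in aln],
        seqs=[str(rec.seq) for rec in aln],
        ss_cons=ss,
    )


def write_stockholm(aln: StructuralAlignment, path):
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=i, description="") for i, s in
         zip(aln.ids, aln.seqs)])
    if aln.ss_cons is not None:
        msa.column_annotations["secondary_structure"] = aln.ss_cons
    AlignIO.write(msa, path, "stockholm")


def average_identity(aln: StructuralAlignment) -> float:
    """Mean pairwise percent identity over co-ungapped columns."""
    if aln.n_seqs < 2:
        raise ValueError("need >= 2 sequences")
    mat = np.array([list(s) for s in aln.seqs])
    gaps = mat == "-"
    vals = []
    for a in range(aln.n_seqs):
        for b in range(a + 1, aln.n_seqs):
            both = ~(gaps[a] | gaps[b])
            n_co = int(both.sum())
            if n_co == 0:
                warnings.warn(
                    f"pair ({aln.ids[a]}, {aln.ids[b]}) shares no "
                    f"co-ungapped columns; skipped")
                continue
            vals.append(100.0 * (mat[a, both] == mat[b, both]).sum() / n_co)
    return float(np.mean(vals))


def map_structure_to_alignment(ref_structure: SecondaryStructure,
                               aln: StructuralAlignment
                               ) -> list[tuple[int, int]]:
    """Map reference pairs (i, j) to alignment column pairs (col_i, col_j)."""
    if aln.ref_seq != ref_structure.sequence:
        raise ValueError(
            "reference sequence of the alignment does not match the "
            "structure's sequence")
    r2c = aln.ref_to_col()
    return [(r2c[i], r2c[j]) for i, j in ref_structure.pair_list()]


# ---------------------------------------------------------------------------
# mutual information with APC and a permutation null
# ---------------------------------------------------------------------------

_MI_ALPHABET = "ACGU"
_SYM_INDEX = {c: k for k, c in enumerate(_MI_ALPHABET)}


def _encode_columns(aln: StructuralAlignment) -> np.ndarray:
    """(n_seqs, n_cols) int matrix; ACGU -> 0..3, gap/other -> -1."""
    mat = np.full((aln.n_seqs, aln.n_cols), -1, dtype=np.int8)
    for r, s in enumerate(aln.seqs):
        for c, ch in enumerate(s):
            mat[r, c] = _SYM_INDEX.get(ch, -1)
    return mat


def _mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    """MI (log2) of two residue vectors (no missing values)."""
    joint = np.bincount(4 * x + y, minlength=16).astype(float).reshape(4, 4)
    m = joint.sum()
    joint /= m
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(
        joint[nz] / np.outer(px, py)[nz])))


def covariation_scores(aln: StructuralAlignment,
                       column_pairs: list[tuple[int, int]]) -> pd.DataFrame:
    """Per-pair MI (bits), APC-corrected MIp and effective depth.

    Gaps are handled by pairwise deletion; a pair with fewer than
    5 co-ungapped sequences scores as undefined (NaN).  The APC term
    ``mean_i * mean_j / grand_mean`` is computed over the scored pair set.
    """
    if aln.n_seqs < MIN_SEQS_FOR_COVARIATION:
        raise ValueError(f"need >= {MIN_SEQS_FOR_COVARIATION} sequences")
    enc = _encode_columns(aln)
    mi = np.full(len(column_pairs), np.nan)
    n_eff = np.zeros(len(column_pairs), dtype=int)
    for k, (a, b) in enumerate(column_pairs):
        xa, xb = enc[:, a - 1], enc[:, b - 1]
        ok = (xa >= 0) & (xb >= 0)
        n_eff[k] = int(ok.sum())
        if n_eff[k] >= MIN_COUNGAPPED:
            mi[k] = _mi_bits(xa[ok], xb[ok])
    # APC over the scored set
    cols = sorted({c for p in column_pairs for c in p})
    col_sum = {c: 0.0 for c in cols}
    col_cnt = {c: 0 for c in cols}
    for (a, b), m in zip(column_pairs, mi):
        if np.isnan(m):
            continue
        col_sum[a] += m
        col_cnt[a] += 1
        col_sum[b] += m
        col_cnt[b] += 1
    defined = mi[~np.isnan(mi)]
    grand = float(defined.mean()) if len(defined) else np.nan
    apc = np.full(len(column_pairs), np.nan)
    for k, (a, b) in enumerate(column_pairs):
        if np.isnan(mi[k]) or not grand:
            continue
        ma = col_sum[a] / col_cnt[a]
        mb = col_sum[b] / col_cnt[b]
        apc[k] = mi[k] - ma * mb / grand
    return pd.DataFrame({
        "col_i": [p[0] for p in column_pairs],
        "col_j": [p[1] for p in column_pairs],
        "MI_bits": mi,
        "APC_corrected": apc,
        "n_effective": n_eff,
    })


def covariation_significance(aln: StructuralAlignment,
                             column_pairs: list[tuple[int, int]],
                             n_perm: int = 1000, fdr: float = 0.05,
                             seed: int = 0) -> pd.DataFrame:
    """Permutation p-values and BH q-values for the MI of each pair.

    The null shuffles residues within each column independently (gaps kept
    in place), destroying inter-column dependence while preserving column
    composition and gap structure: ``p = (1 + #null >= observed) /
    (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives an unstable p-value floor")
    scores = covariation_scores(aln, column_pairs)
    enc = _encode_columns(aln)
    rng = np.random.default_rng(seed)
    pvals = np.full(len(column_pairs), np.nan)
    for k, (a, b) in enumerate(column_pairs):
        obs = scores["MI_bits"].iloc[k]
        if np.isnan(obs):
            continue
        xa, xb = enc[:, a - 1].copy(), enc[:, b - 1].copy()
        ia, ib = np.flatnonzero(xa >= 0), np.flatnonzero(xb >= 0)
        hits = 0
        for _ in range(n_perm):
            pa, pb = xa.copy(), xb.copy()
            pa[ia] = xa[ia][rng.permutation(len(ia))]
            pb[ib] = xb[ib][rng.permutation(len(ib))]
            ok = (pa >= 0) & (pb >= 0)
            if _mi_bits(pa[ok], pb[ok]) >= obs - 1e-12:
                hits += 1
        pvals[k] = (1.0 + hits) / (1.0 + n_perm)
    out = scores.copy()
    out["p"] = pvals
    q = np.full(len(pvals), np.nan)
    defined = ~np.isnan(pvals)
    if defined.any():
        q[defined] = multipletests(pvals[defined], method="fdr_bh")[1]
    out["q"] = q
    out["significant"] = (out["q"] <= fdr).fillna(False)
    return out
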