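"""Per-nucleotide chemical reactivity profiles.

A :class:`ReactivityProfile` holds one RNA's normalized (or raw) reactivities
for one probing reagent.  SHAPE reagents report backbone flexibility at every
nucleotide; DMS reports the Watson-Crick face of single-stranded A and C only,
so DMS profiles carry ``NO_DATA`` at every G/U position.  Positions that could
not be measured (high background, dropout) are ``NO_DATA`` — represented
internally as ``nan`` and externally as the community sentinel ``-999``.
``NO_DATA`` is never treated as zero.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

NO_DATA = float("nan")
#: external sentinel used by the .shape/.map dialects
NO_DATA_SENTINEL = -999.0

_RNA_COMPLEMENT_OK = set("ACGU")


class ProfileFormatError(ValueError):
    """Malformed .shape/.map file."""


class InsufficientDataError(ValueError):
    """Too few measured values for the requested statistic."""


class DegenerateProfileError(ValueError):
    """Normalization divisor is not positive."""


def is_no_data(x) -> np.ndarray | bool:
    """True where a reactivity value is the NO_DATA marker."""
    return np.isnan(x)


def clean_sequence(seq: str) -> str:
    """Uppercase, DNA->RNA (T->U); reject anything outside ACGUT."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_COMPLEMENT_OK
    if bad:
        raise ValueError(f"sequence contains non-ACGU(T) symbols: {sorted(bad)}")
    return s


@dataclass
class ReactivityProfile:
    """Reactivities for one RNA and one reagent.

    Parameters
    ----------
    rna_id : str
        Identifier of the transcript.
    sequence : str
        RNA sequence, stored uppercase with T converted to U.  May be empty
        when the input dialect does not carry nucleotide identities.
    reactivities : ndarray of float
        One value per nucleotide; ``nan`` marks NO_DATA.  Negative raw values
        (possible upstream of normalization) are clamped to 0 on construction
        because the pseudo-energy term requires r >= 0.
    reagent : {"SHAPE", "DMS"}
    offset : int
        1-based coordinate of the first position.
    """

    rna_id: str
    sequence: str
    reactivities: np.ndarray
    reagent: str = "SHAPE"
    offset: int = 1

    def __post_init__(self):
        self.reactivities = np.asarray(self.reactivities, dtype=float).copy()
        if self.reagent not in ("SHAPE", "DMS"):
            raise ValueError(f"unknown reagent {self.reagent!r}")
        if self.sequence:
            self.sequence = clean_sequence(self.sequence)
            if len(self.sequence) != len(self.reactivities):
                raise ValueError(
                    f"sequence length {len(self.sequence)} != "
                    f"{len(self.reactivities)} reactivities"
                )
            if self.reagent == "DMS":
                # DMS does not report G/U
                gu = np.array([b in "GU" for b in self.sequence])
                self.reactivities[gu] = NO_DATA
        defined = ~np.isnan(self.reactivities)
        neg = defined & (self.reactivities < 0)
        self.reactivities[neg] = 0.0

    def __len__(self) -> int:
        return len(self.reactivities)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.reactivities)

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())

    def slice(self, start: int, end: int) -> "ReactivityProfile":
        """1-based inclusive sub-profile (coordinates relative to offset)."""
        a = start - self.offset
        b = end - self.offset + 1
        if a < 0 or b > len(self):
            raise IndexError(f"slice {start}-{end} outside profile")
        return ReactivityProfile(
            rna_id=f"{self.rna_id}:{start}-{end}",
            sequence=self.sequence[a:b] if self.sequence else "",
            reactivities=self.reactivities[a:b],
            reagent=self.reagent,
            offset=start,
        )

    def with_reactivities(self, values: np.ndarray) -> "ReactivityProfile":
        return replace(self, reactivities=np.asarray(values, dtype=float))

    def normalized(self) -> "ReactivityProfile":
        return self.with_reactivities(normalize_reactivities(self.reactivities))


# ---------------------------------------------------------------------------
# file I/O: .shape (position reactivity) and .map (position reactivity stderr
# nucleotide), whitespace/tab-delimited, -999 (or nan) as NO_DATA
# ---------------------------------------------------------------------------

def read_shape_file(path, dialect: str = "shape", rna_id: str = "",
                    reagent: str = "SHAPE") -> ReactivityProfile:
    """Read a .shape or .map reactivity table.

    ``.shape`` rows are ``position reactivity``; ``.map`` rows are
    ``position reactivity stderr nucleotide`` (the nucleotide column, when
    present, populates the profile's sequence).  Positions must be contiguous
    ascending.  ``-999`` and ``nan`` become NO_DATA.
    """
    if dialect not in ("shape", "map"):
        raise ValueError(f"unknown dialect {dialect!r}")
    values: list[float] = []
    bases: list[str] = []
    expected = None
    first = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ProfileFormatError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                pos = int(parts[0])
                val = float(parts[1])
            except ValueError as exc:
                raise ProfileFormatError(f"{path}:{lineno}: {exc}") from None
            if first is None:
                first = pos
                expected = pos
            if pos != expected:
                raise ProfileFormatError(
                    f"{path}:{lineno}: non-contiguous position {pos} "
                    f"(expected {expected})"
                )
            expected += 1
            if math.isnan(val) or val == NO_DATA_SENTINEL:
                values.append(NO_DATA)
            elif val < 0:
                raise ProfileFormatError(
                    f"{path}:{lineno}: negative reactivity {val} is not the "
                    f"{NO_DATA_SENTINEL:g} sentinel"
                )
            else:
                values.append(val)
            if dialect == "map":
                if len(parts) < 4:
                    raise ProfileFormatError(
                        f"{path}:{lineno}: .map rows need 4 columns")
                bases.append(parts[3])
    if not values:
        raise ProfileFormatError(f"{path}: empty reactivity file")
    sequence = "".join(bases) if dialect == "map" else ""
    return ReactivityProfile(rna_id=rna_id or str(path), sequence=sequence,
                             reactivities=np.array(values), reagent=reagent,
                             offset=first)


def write_shape_file(profile: ReactivityProfile, path, dialect: str = "shape"):
    """Write a profile in the .shape or .map dialect (roundtrip-exact).

    Values are printed with ``repr`` so read-back reproduces each float
    bit-exactly.
    """
    if dialect not in ("shape", "map"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "map" and not profile.sequence:
        raise ValueError(".map output requires a sequence")
    with open(path, "w") as fh:
        for k, v in enumerate(profile.reactivities):
            pos = profile.offset + k
            sval = f"{NO_DATA_SENTINEL:g}" if math.isnan(v) else repr(float(v))
            if dialect == "shape":
                fh.write(f"{pos}\t{sval}\n")
            else:
                fh.write(f"{pos}\t{sval}\t0\t{profile.sequence[k]}\n")


def profile_table(profile: ReactivityProfile):
    """Combined per-nucleotide table (position, base, reactivity, reagent)."""
    import pandas as pd

    n = len(profile)
    return pd.DataFrame({
        "position": np.arange(profile.offset, profile.offset + n),
        "base": list(profile.sequence) if profile.sequence else [""] * n,
        "reactivity": profile.reactivities,
        "reagent": profile.reagent,
    })


# ---------------------------------------------------------------------------
# normalization and correlation
# ---------------------------------------------------------------------------

MIN_DEFINED_FOR_NORM = 20


def normalize_reactivities(raw: np.ndarray) -> np.ndarray:
    """2%/8% normalization of a raw reactivity vector.

    Defined values are sorted descending; the top 2% are excluded and the
    vector is divided by the mean of the next 8% (at least one value).
    NO_DATA passes through unchanged.  The operation is idempotent and
    invariant to positive rescaling of the input.
    """
    raw = np.asarray(raw, dtype=float)
    defined = ~np.isnan(raw)
    n_def = int(defined.sum())
    if n_def < MIN_DEFINED_FOR_NORM:
        raise InsufficientDataError(
            f"need >= {MIN_DEFINED_FOR_NORM} measured values, got {n_def}")
    vals = np.sort(raw[defined])[::-1]
    n_excl = int(n_def * 0.02)
    n_avg = max(1, int(n_def * 0.08))
    divisor = float(np.mean(vals[n_excl:n_excl + n_avg]))
    if divisor <= 0:
        raise DegenerateProfileError(
            f"2%/8% normalization divisor {divisor} is not positive")
    return raw / divisor


def pearson_r(x, y) -> tuple[float, int]:
    """Pearson correlation with pairwise NO_DATA deletion.

    Returns ``(r, n_used)``.  Raises on fewer than 3 usable pairs or zero
    variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    n_used = int(ok.sum())
    if n_used < 3:
        raise InsufficientDataError(f"only {n_used} usable pairs (need >= 3)")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateProfileError("zero variance: correlation undefined")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, n_used
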