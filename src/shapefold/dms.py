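"""DMS-based validation of a structural model.

DMS methylates the Watson-Crick face of single-stranded adenosines and
cytidines, so high DMS reactivity at an A/C argues that position is not in
the interior of a helix.  Reactivities are binned into low / intermediate /
high classes, and the agreement statistic is the percentage of highly
reactive A/C nucleotides that the model places in loops or at helix termini
(the terminal base pairs of a maximal stack, which breathe).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fold import SecondaryStructure
from .profiles import ReactivityProfile

DMS_LOW = 0.4
DMS_HIGH = 0.85


class UndefinedStatisticError(ValueError):
    """No highly reactive positions: the agreement percentage is undefined."""


def _require_dms(profile: ReactivityProfile):
    if profile.reagent != "DMS":
        raise ValueError(f"expected a DMS profile, got reagent "
                         f"{profile.reagent!r}")


def classify_dms(profile: ReactivityProfile, low: float = DMS_LOW,
                 high: float = DMS_HIGH) -> dict:
    """Bin A/C reactivities into low (< low), mid ([low, high]), high (> high).

    Boundary values fall in the middle class.  Positions without data are
    excluded.  Returns counts and the per-position class table.
    """
    _require_dms(profile)
    r = profile.reactivities
    defined = profile.defined_mask
    classes = np.full(len(r), "", dtype=object)
    classes[defined & (r < low)] = "low"
    classes[defined & (r >= low) & (r <= high)] = "mid"
    classes[defined & (r > high)] = "high"
    table = pd.DataFrame({
        "position": np.arange(profile.offset, profile.offset + len(r)),
        "base": list(profile.sequence) if profile.sequence else [""] * len(r),
        "reactivity": r,
        "dms_class": classes,
    })
    return {
        "n_low": int((classes == "low").sum()),
        "n_mid": int((classes == "mid").sum()),
        "n_high": int((classes == "high").sum()),
        "table": table,
    }


def helix_terminus_positions(structure: SecondaryStructure) -> set[int]:
    """1-based positions in the first or last pair of each maximal helix.

    An isolated pair is a helix of length one: both its positions are
    termini.
    """
    structure.validate()
    out: set[int] = set()
    for helix in structure.helices():
        for i, j in (helix[0], helix[-1]):
            out.add(i)
            out.add(j)
    return out


def agreement_statistic(structure: SecondaryStructure,
                        dms: ReactivityProfile,
                        high: float = DMS_HIGH) -> dict:
    """Percent of highly DMS-reactive A/Cs that are unpaired or at helix
    termini — the model/data agreement statistic."""
    _require_dms(dms)
    if len(dms) != len(structure):
        raise ValueError("profile and structure lengths differ")
    r = dms.reactivities
    high_pos = np.flatnonzero(dms.defined_mask & (r > high))  # 0-based
    if len(high_pos) == 0:
        raise UndefinedStatisticError(
            "no highly reactive nucleotides: agreement undefined")
    termini = helix_terminus_positions(structure)
    ok = sum(1 for p in high_pos
             if structure.partner[p] < 0 or (p + 1) in termini)
    return {
        "percent_agree": 100.0 * ok / len(high_pos),
        "n_high": int(len(high_pos)),
        "n_agree": int(ok),
    }
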