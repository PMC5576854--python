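"""Small reporting utilities: collection totals, shares, group contrasts.

These back the run report's headline numbers (how many specimens each
method yielded, what share was identifiable to species, how much lower a
metric is in one treatment than the other) and are deliberately tiny,
exact integer/ratio arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["share", "relative_difference", "collection_summary"]


def share(part: float, whole: float, digits: int = 1) -> float:
    """Percentage ``100 * part / whole`` rounded to `digits` decimals."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, digits)


def relative_difference(reference: float, other: float, digits: int = 1) -> float:
    """How much lower (positive) or higher (negative) `other` is than
    `reference`, as a percentage of `reference`."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return round(100.0 * (reference - other) / reference, digits)


def collection_summary(records: pd.DataFrame) -> dict:
    """Headline counts for a validated survey table.

    Totals and per-method specimen/species tallies, with percentages of
    the method-covered total (specimens) and of the overall species
    count (species), plus the identification-level breakdown of
    individuals.
    """
    total = int(records["count"].sum())
    n_species = int(records["species_id"].nunique())
    out = {"total_specimens": total, "total_species": n_species, "methods": {}}
    for method, grp in records.groupby("method"):
        out["methods"][method] = {
            "specimens": int(grp["count"].sum()),
            "specimens_pct": share(grp["count"].sum(), total),
            "species": int(grp["species_id"].nunique()),
            "species_pct": share(grp["species_id"].nunique(), n_species),
        }
    levels = records.groupby("id_level")["count"].sum()
    out["id_levels"] = {
        lvl: {"specimens": int(n), "pct": share(n, total)}
        for lvl, n in levels.items()
    }
    return out
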