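"""Realized-cell-count quality control for hot-spot apps.

An app targets a cell count, but with a fixed region size the realized
count depends on local tumor density, so dense slides overshoot the
target.  Apps whose *median* realized count across the cohort exceeds a
configurable multiple of the target are flagged for exclusion.
"""

from __future__ import annotations

import pandas as pd

from .registry import get_app

DEFAULT_OVERSHOOT_FACTOR = 2.0


def qc_realized_counts(results: pd.DataFrame,
                       factor: float = DEFAULT_OVERSHOOT_FACTOR) -> pd.DataFrame:
    """Summarise realized hot-spot cell counts per app and flag overshoots.

    Parameters
    ----------
    results : DataFrame
        Long table with columns ``app_id``, ``slide_id``, ``status`` and
        ``n_cells`` (one row per app x slide).
    factor : float
        An app is flagged when its median realized count exceeds
        ``factor * min_cells``.

    Returns
    -------
    DataFrame indexed by app_id with columns ``min_cells``, ``n_slides``,
    ``median_cells``, ``min_cells_seen``, ``max_cells_seen``, ``flagged``.
    """
    required = {"app_id", "slide_id", "status", "n_cells"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    ok = results[results["status"] == "ok"]
    rows = []
    for app_id, grp in ok.groupby("app_id", sort=True):
        target = get_app(app_id).min_cells
        med = float(grp["n_cells"].median())
        rows.append({
            "app_id": app_id,
            "min_cells": target,
            "n_slides": int(len(grp)),
            "median_cells": med,
            "min_cells_seen": int(grp["n_cells"].min()),
            "max_cells_seen": int(grp["n_cells"].max()),
            "flagged": bool(med > factor * target),
        })
    return pd.DataFrame(rows).set_index("app_id")


def flagged_apps(report: pd.DataFrame) -> list[str]:
    """App ids flagged by :func:`qc_realized_counts`."""
    return sorted(report.index[report["flagged"]])
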