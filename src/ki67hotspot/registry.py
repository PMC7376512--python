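"""Registry of the 22 hot-spot app configurations.

Each app combines four parameters: target tumor-cell count, field of
view (drawing radius), heatmap basis (positive count vs positive ratio)
and region shape (circle vs contour).  The full factorial of the two
initial cell counts (200/1000), two radii, two bases and two shapes is
16 apps; the two combining 1000 cells with the small 40x circle were
dropped before any analysis, and eight contour apps at intermediate
counts (400-1200) were added, giving 22.  Three circular positive-basis
apps are excluded after quality control because their realized cell
counts far exceed the configured targets.
"""

from __future__ import annotations

from .types import HotspotConfig

# (app_id, min_cells, fov, basis, shape)
_TABLE = (
    ("APP02", 200, "40x", "positive", "circle"),
    ("APP03", 1000, "20x", "positive", "circle"),
    ("APP04", 200, "20x", "positive", "circle"),
    ("APP05", 1000, "20x", "ratio", "circle"),
    ("APP06", 200, "20x", "ratio", "circle"),
    ("APP08", 200, "40x", "ratio", "circle"),
    ("APP09", 1000, "20x", "positive", "contour"),
    ("APP10", 200, "20x", "positive", "contour"),
    ("APP11", 1000, "40x", "positive", "contour"),
    ("APP12", 200, "40x", "positive", "contour"),
    ("APP13", 1000, "20x", "ratio", "contour"),
    ("APP14", 200, "20x", "ratio", "contour"),
    ("APP15", 1000, "40x", "ratio", "contour"),
    ("APP16", 200, "40x", "ratio", "contour"),
    ("APP20", 400, "40x", "ratio", "contour"),
    ("APP21", 600, "40x", "ratio", "contour"),
    ("APP22", 800, "40x", "ratio", "contour"),
    ("APP23", 1200, "40x", "ratio", "contour"),
    ("APP24", 400, "40x", "positive", "contour"),
    ("APP25", 600, "40x", "positive", "contour"),
    ("APP26", 800, "40x", "positive", "contour"),
    ("APP27", 1200, "40x", "positive", "contour"),
)

#: Apps removed after realized-cell-count quality control.
QC_EXCLUDED_APPS = ("APP02", "APP03", "APP04")

#: App groups used for reproducibility (ICC) analysis, by target count.
ICC_GROUPS = {
    "low_~200": ("APP06", "APP08", "APP10", "APP12", "APP14", "APP16"),
    "mid_400-800": ("APP20", "APP21", "APP22", "APP24", "APP25", "APP26"),
    "high_~1000": ("APP05", "APP09", "APP13", "APP23", "APP27"),
}


def app_registry() -> list[HotspotConfig]:
    """Return the 22 hot-spot app configurations."""
    return [HotspotConfig(*row) for row in _TABLE]


def post_qc_apps() -> list[HotspotConfig]:
    """The 19 apps remaining after count-overshoot quality control."""
    return [c for c in app_registry() if c.app_id not in QC_EXCLUDED_APPS]


def get_app(app_id: str) -> HotspotConfig:
    """Look up one app by id (raises KeyError for unknown ids)."""
    for cfg in app_registry():
        if cfg.app_id == app_id:
            return cfg
    raise KeyError(f"unknown hot-spot app {app_id!r}")
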