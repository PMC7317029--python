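"""Default registry of phenotype score categories.

The screen database scores each animal on 33 ordinal categories describing
aspects of clone/tumor behavior relative to the sensitized background.  Only a
subset of the category names is fixed by convention (they are referenced by
downstream stages, e.g. the invasion-network seed categories); the remainder of
the default registry is a set of descriptive placeholders that users replace
with their own names.  The registry is an ordered list; order defines column
order in exported matrices.
"""

from __future__ import annotations

# Categories referenced by name elsewhere in the pipeline.
INVASION = "invasion"
MULTILAYERING = "multilayering"
CELL_BODY_ROUNDING = "cell body rounding"

#: Seed categories used to build the invasion-suppressor network.
NETWORK_SEED_CATEGORIES = (INVASION, MULTILAYERING, CELL_BODY_ROUNDING)

#: Default 33-entry category registry.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "clone size",
    "clone shape",
    INVASION,
    MULTILAYERING,
    CELL_BODY_ROUNDING,
    "number of dividing cells",
    "apex size",
    "apex defects",
    "junction defects",
    "cytoskeletal defects",
    "basal protrusions",
    "microvilli defects",
    "membrane blebbing",
    "actin accumulation",
    "polarized actin spots",
    "delamination",
    "clone coverage",
    "clone fragmentation",
    "cell death",
    "cell size",
    "cell shape irregularity",
    "nuclear position",
    "tissue folding",
    "clone border smoothness",
    "apical constriction",
    "basal extrusion",
    "cell crowding",
    "mitotic orientation",
    "cytokinesis defects",
    "lamellipodia",
    "filopodia",
    "cell-cell adhesion defects",
    "tissue tension",
)

assert len(DEFAULT_CATEGORIES) == 33


def validate_registry(categories) -> tuple[str, ...]:
    """Return ``categories`` as a tuple after checking uniqueness."""
    cats = tuple(categories)
    if len(set(cats)) != len(cats):
        raise ValueError("category registry contains duplicate names")
    if not cats:
        raise ValueError("category registry is empty")
    return cats
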