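"""Functional-group overlay and deepwater exclusion.

Lakes, reservoirs and river channels are partially filtered before modelling:
pixels of the raw ``lake`` and ``riparian`` classes that carry semi-permanent
hydroperiods are perennial deep water and are dropped, while their temporary
and seasonal fringes are kept — surviving lake pixels become littoral (or
littoral-saline for saline lakes such as the Great Salt Lake) and surviving
riparian pixels are folded into the palustrine class.  The filtered labels
are then intersected with a species' annual-cycle water mask to produce the
twelve binary covariate layers used by the abundance model, with cultivated
rice excluded from the total "wetland area" layer.
"""

from __future__ import annotations

import numpy as np

from .grids import (
    COVARIATES,
    FUNC_CLASS_CODES,
    FUNC_LAKE,
    FUNC_LITTORAL,
    FUNC_LITTORAL_SALINE,
    FUNC_NONE,
    FUNC_PALUSTRINE,
    FUNC_RICE,
    FUNC_RIPARIAN,
    FUNCTIONAL_COVARIATES,
    HYDRO_SEASONAL,
    HYDRO_SEMI_PERMANENT,
    HYDRO_TEMPORARY,
    FunctionalGroupGrid,
    HydroperiodGrid,
)

_HYDRO_COVARIATE_CODES = {
    "temporary": HYDRO_TEMPORARY,
    "seasonal": HYDRO_SEASONAL,
    "semi_permanent": HYDRO_SEMI_PERMANENT,
}


def apply_deepwater_exclusion(
    groups: FunctionalGroupGrid,
    hydro: HydroperiodGrid,
    saline_lakes: np.ndarray | None = None,
) -> FunctionalGroupGrid:
    """Remove perennial deep water from lake and riparian classes.

    ``saline_lakes`` flags lake pixels belonging to saline systems; their
    surviving fringes map to littoral-saline instead of littoral.  The
    operation is idempotent: its output contains no lake or riparian labels.
    """
    if groups.labels.shape != hydro.classes.shape:
        raise ValueError("functional and hydroperiod grids differ in shape")
    labels = groups.labels.copy()
    semi = hydro.classes == HYDRO_SEMI_PERMANENT
    lake = labels == FUNC_LAKE
    riparian = labels == FUNC_RIPARIAN
    labels[(lake | riparian) & semi] = FUNC_NONE
    survivors = lake & ~semi
    if saline_lakes is not None:
        saline_lakes = np.asarray(saline_lakes, dtype=bool)
        labels[survivors & saline_lakes] = FUNC_LITTORAL_SALINE
        labels[survivors & ~saline_lakes] = FUNC_LITTORAL
    else:
        labels[survivors] = FUNC_LITTORAL
    # riparian is not a model predictor; non-deepwater survivors behave like
    # unmanaged freshwater palustrine wetlands
    labels[riparian & ~semi] = FUNC_PALUSTRINE
    return FunctionalGroupGrid(labels=labels, geometry=groups.geometry)


def build_covariate_layers(
    groups: FunctionalGroupGrid,
    hydro: HydroperiodGrid,
    cycle_mask: np.ndarray,
) -> dict[str, np.ndarray]:
    """Binary fine-grid layers for the twelve model covariates.

    Hydroperiod covariates are class membership within the cycle water mask;
    functional covariates likewise; ``wetland_area`` is the cycle mask minus
    rice pixels.  Requires the deepwater exclusion to have been applied.
    """
    if groups.labels.shape != hydro.classes.shape:
        raise ValueError("functional and hydroperiod grids differ in shape")
    cycle_mask = np.asarray(cycle_mask, dtype=bool)
    if cycle_mask.shape != groups.labels.shape:
        raise ValueError("cycle mask shape mismatch")
    if np.any(groups.labels == FUNC_LAKE) or np.any(groups.labels == FUNC_RIPARIAN):
        raise ValueError("deepwater exclusion must be applied before layer building")

    layers: dict[str, np.ndarray] = {}
    rice = groups.labels == FUNC_RICE
    layers["wetland_area"] = cycle_mask & ~rice
    for name, code in _HYDRO_COVARIATE_CODES.items():
        layers[name] = (hydro.classes == code) & cycle_mask
    for name in FUNCTIONAL_COVARIATES:
        layers[name] = (groups.labels == FUNC_CLASS_CODES[name]) & cycle_mask
    assert set(layers) == set(COVARIATES)
    return layers
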