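"""Load partition across the trunks by composite theory.

A tensile force of ``load_multiplier`` times the single-root rupture load
is divided between the three trunks in proportion to cross-sectional
area (all trunks share one Young's modulus, so area ratios equal
stiffness ratios).  Root cross-sections are ellipses with the
cranial-caudal and transverse diameters as axes; trunk areas are the
sums of their member-root areas (tissue cross-section conserved as roots
combine).  Because area enters both the force split and the
force-to-pressure conversion, every trunk sees the same distal pressure
``p = multiplier * F_fail / sum(root areas)``.

Two loading-rate cases are bundled: quasistatic (0.01 mm/s) and dynamic
(10 mm/s) stretch, with rate-matched rupture load and modulus from
neonatal piglet tensile tests.  The tabulated pressures (0.332 and
0.653 MPa) are carried as the authoritative applied values; the value
recomputed from the areas is a cross-check and agrees within 0.2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .anatomy import ROOT_IDS, TRUNK_IDS, TRUNK_MEMBERS, RootDimensions


@dataclass(frozen=True)
class LoadCase:
    """One loading-rate condition: rate, rupture load, elastic constants,
    and the tabulated distal-trunk pressure (MPa)."""

    case_id: str
    loading_rate: float        # mm/s
    rupture_load: float        # N, single-root failure load F_fail
    load_multiplier: float     # total force = multiplier * F_fail
    youngs_modulus: float      # MPa
    poisson_ratio: float
    applied_pressure: float    # MPa, tabulated value used in the solves

    def __post_init__(self):
        if self.rupture_load <= 0:
            raise ValueError("rupture load must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")


#: Quasistatic and dynamic stretch conditions with the tabulated pressures.
DEFAULT_LOAD_CASES: dict[str, LoadCase] = {
    "case1": LoadCase("case1", 0.01, 1.08, 5.0, 1.48, 0.4, 0.332),
    "case2": LoadCase("case2", 10.0, 2.12, 5.0, 2.02, 0.4, 0.653),
}


def ellipse_area(d_cc: float, d_t: float) -> float:
    """Ellipse cross-section area (mm^2) from the two diameters."""
    if d_cc <= 0 or d_t <= 0:
        raise ValueError("diameters must be positive")
    return math.pi / 4.0 * d_cc * d_t


def root_areas(dims: dict[str, RootDimensions]) -> dict[str, float]:
    return {rid: ellipse_area(dims[rid].d_cranial_caudal, dims[rid].d_transverse)
            for rid in ROOT_IDS}


def trunk_areas(dims: dict[str, RootDimensions]) -> dict[str, float]:
    """Trunk cross-section areas: sums of member-root ellipse areas (mm^2)."""
    areas = root_areas(dims)
    return {tid: sum(areas[r] for r in TRUNK_MEMBERS[tid]) for tid in TRUNK_IDS}


def applied_pressure(case: LoadCase, dims: dict[str, RootDimensions]) -> float:
    """Distal-trunk pressure (MPa) computed from the areas: the same value
    for every trunk because area cancels between force share and area
    normalisation."""
    total = sum(root_areas(dims).values())
    if total <= 0:
        raise ValueError("total cross-sectional area must be positive")
    return case.load_multiplier * case.rupture_load / total


def trunk_force(pressure: float, trunk_area: float) -> float:
    """Axial force (N) carried by a trunk of the given area under ``pressure``."""
    if pressure < 0 or trunk_area <= 0:
        raise ValueError("pressure must be >= 0 and area > 0")
    return pressure * trunk_area


def load_partition_table(case: LoadCase,
                         dims: dict[str, RootDimensions]) -> pd.DataFrame:
    """Per-trunk area/force/pressure report (CSV-ready)."""
    p = applied_pressure(case, dims)
    tareas = trunk_areas(dims)
    rows = [{"trunk": tid,
             "area_mm2": tareas[tid],
             "pressure_MPa": p,
             "force_N": trunk_force(p, tareas[tid])}
            for tid in TRUNK_IDS]
    df = pd.DataFrame(rows)
    df.attrs["case_id"] = case.case_id
    df.attrs["tabulated_pressure_MPa"] = case.applied_pressure
    return df
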