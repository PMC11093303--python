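"""Extraction of the reported study quantities.

Per-root maximum junction von Mises stress (over the elements adjacent
to the root-cord interface), per-trunk distal displacement (magnitude of
the mean displacement over the distal face nodes), engineering strain
(distal displacement over original cord-to-trunk path length) and
percent change against a baseline.

Reporting precision follows the study tables: stresses to 3 decimals
(MPa), strains to one decimal (%), percent changes to the nearest
integer with an explicit sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import ROOT_IDS, TRUNK_IDS
from .errors import TaggingError
from .meshing import Mesh
from .solver import Solution, StressField


def junction_elements(mesh: Mesh, root_id: str) -> np.ndarray:
    """Global ids of elements sharing at least one node with the root-cord
    interface edge set of ``root_id``."""
    name = f"junction_{root_id}"
    if name not in mesh.edge_sets or not mesh.edge_sets[name]:
        raise TaggingError(f"junction edge set for {root_id} is empty")
    jn = set(int(n) for n in mesh.edge_set_nodes(name))
    out = [e for e in range(mesh.n_elements)
           if jn.intersection(int(n) for n in mesh.element_nodes(e))]
    if not out:
        raise TaggingError(f"no elements adjacent to junction of {root_id}")
    return np.asarray(out, dtype=np.int64)


def nodal_averaged_von_mises(stress: StressField, mesh: Mesh,
                             node_ids) -> np.ndarray:
    """Contour-style nodal values: mean of the centroid von Mises of the
    elements incident to each node (the patch value a stress-contour
    display reports at a node)."""
    wanted = set(int(n) for n in node_ids)
    sums = {n: 0.0 for n in wanted}
    counts = {n: 0 for n in wanted}
    for e in range(mesh.n_elements):
        ve = float(stress.von_mises_centroid[e])
        for n in mesh.element_nodes(e):
            n = int(n)
            if n in wanted:
                sums[n] += ve
                counts[n] += 1
    return np.array([sums[int(n)] / max(counts[int(n)], 1)
                     for n in node_ids])


def max_junction_stress(stress: StressField, mesh: Mesh, root_id: str,
                        measure: str = "nodal_avg") -> float:
    """Maximum von Mises stress (MPa) at the root-cord junction.

    ``measure`` selects how the junction value is sampled:

    * ``"nodal_avg"`` (default) - largest contour-style nodal value over
      the interface nodes, i.e. the element-averaged patch value a
      stress-contour display reports where the root joins the cord;
    * ``"centroid"`` - largest element centroid value among the elements
      adjacent to the interface;
    * ``"max_gp"`` - largest Gauss-point value among those elements.
    """
    if measure == "nodal_avg":
        name = f"junction_{root_id}"
        if name not in mesh.edge_sets or not mesh.edge_sets[name]:
            raise TaggingError(f"junction edge set for {root_id} is empty")
        vals = nodal_averaged_von_mises(stress, mesh,
                                        mesh.edge_set_nodes(name))
        return float(vals.max())
    elems = junction_elements(mesh, root_id)
    vm = {"centroid": stress.von_mises_centroid,
          "max_gp": stress.von_mises_max_gp}[measure]
    return float(vm[elems].max())


def distal_displacement(sol: Solution, mesh: Mesh, trunk: str) -> float:
    """Magnitude (mm) of the mean displacement over the trunk's distal face."""
    name = f"distal_{trunk}"
    if name not in mesh.edge_sets or not mesh.edge_sets[name]:
        raise TaggingError(f"distal edge set for trunk {trunk!r} is empty")
    nodes = mesh.edge_set_nodes(name)
    return float(np.linalg.norm(sol.displacements[nodes].mean(axis=0)))


def engineering_strain(displacement: float, original_length: float) -> float:
    """Engineering strain in percent, reported to one decimal."""
    if original_length <= 0:
        raise ValueError("original length must be positive")
    return round(100.0 * displacement / original_length, 1)


def percent_change(variant: float, baseline: float) -> int:
    """Signed integer percent change of ``variant`` against ``baseline``."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return int(round(100.0 * (variant - baseline) / baseline))


def format_percent_change(variant: float, baseline: float) -> str:
    """Table-style string, e.g. ``"-44%"`` or ``"+67%"``."""
    pc = percent_change(variant, baseline)
    return f"{pc:+d}%"


@dataclass
class StudyResult:
    """Quantities reported for one solved configuration."""

    case_id: str
    label: str                                  # e.g. "baseline" or "delta+3"
    root_stresses: dict[str, float]             # MPa, max junction von Mises
    trunk_displacements: dict[str, float]       # mm, distal face
    trunk_strains: dict[str, float]             # %, vs original path length
    path_lengths: dict[str, float]              # mm, cord to distal trunk
    percent_changes: dict[str, int] = field(default_factory=dict)
    equilibrium_residual: float = float("nan")

    def attach_baseline(self, baseline: "StudyResult"):
        self.percent_changes = {
            rid: percent_change(self.root_stresses[rid],
                                baseline.root_stresses[rid])
            for rid in ROOT_IDS}
        return self

    def stresses_frame(self) -> pd.DataFrame:
        row = {rid: round(self.root_stresses[rid], 3) for rid in ROOT_IDS}
        return pd.DataFrame([row], index=[f"{self.case_id}:{self.label}"])

    def trunks_frame(self) -> pd.DataFrame:
        rows = []
        for tid in TRUNK_IDS:
            rows.append({
                "trunk": tid,
                "original_length_mm": round(self.path_lengths[tid], 1),
                "predicted_displacement_mm": round(self.trunk_displacements[tid], 1),
                "predicted_strain_pct": self.trunk_strains[tid],
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "label": self.label,
            "root_stresses_MPa": {r: round(v, 6)
                                  for r, v in self.root_stresses.items()},
            "trunk_displacements_mm": {t: round(v, 6)
                                       for t, v in self.trunk_displacements.items()},
            "trunk_strains_pct": dict(self.trunk_strains),
            "path_lengths_mm": dict(self.path_lengths),
            "percent_changes_pct": dict(self.percent_changes),
            "equilibrium_residual": self.equilibrium_residual,
        }


def angle_sweep_frame(results: dict[float, StudyResult]) -> pd.DataFrame:
    """Sweep table: rows = roots, columns = angle deltas, cells carry the
    stress and (for non-baseline columns) the percent change."""
    deltas = sorted(results)
    data = {}
    for d in deltas:
        res = results[d]
        col = []
        for rid in ROOT_IDS:
            s = f"{res.root_stresses[rid]:.3f}"
            if d != 0 and rid in res.percent_changes:
                s += f" ({res.percent_changes[rid]:+d}%)"
            col.append(s)
        name = "original" if d == 0 else f"{d:+g} deg"
        data[name] = col
    return pd.DataFrame(data, index=list(ROOT_IDS))
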