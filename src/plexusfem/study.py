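"""Study orchestration: baseline validation runs and the angle sweep.

Phase one solves the baseline anatomy under the quasistatic and dynamic
load cases on one mesh (the dynamic results must equal the quasistatic
ones scaled by the pressure ratio, which is asserted internally).  Phase
two perturbs all five root angles simultaneously by each configured
delta, re-meshes, re-solves the quasistatic case and reports per-root
junction stresses with percent changes against the unperturbed anatomy.
"""

from __future__ import annotations

import json
from pathlib import Path

from .anatomy import (ROOT_IDS, TRUNK_IDS, PlexusGeometry,
                      path_length, perturb_root_angles)
from .config import PlexusConfig, load_config
from .errors import GeometryInfeasibleError, MeshError, PlexusError
from .loading import LoadCase
from .meshing import Mesh, generate_mesh
from .postprocess import (StudyResult, distal_displacement,
                          engineering_strain, max_junction_stress)
from .solver import (BoundaryConditions, MaterialProperties, Solution,
                     StressField, assemble_and_solve)

#: relative tolerance for the internal case2/case1 linearity check
_RATIO_TOL = 1e-6


def make_boundary_conditions(geom: PlexusGeometry, mesh: Mesh,
                             pressure: float,
                             guided_fraction: float = 0.5) -> BoundaryConditions:
    """Model boundary conditions: cord midline encastre, guided
    (transverse-fixed) supports on the superior C5 and inferior T1
    edge portions, and the distal-trunk pressure pulling along each
    trunk axis.

    ``guided_fraction`` is the distal portion of the outermost lateral
    edges that carries the guided support (1.0 = the whole edge); the
    supported portion is measured from the distal end of the edge.
    """
    bcs = BoundaryConditions()
    fixed = set(int(n) for n in mesh.edge_set_nodes("cord_midline"))
    bcs.fix_nodes(sorted(fixed))
    for name, rid in (("superior_edge", "C5"), ("inferior_edge", "T1")):
        normal = geom.roots[rid].normal
        chain = [int(n) for n in mesh.edge_set_nodes(name)]
        k = len(chain) - int(round(guided_fraction * (len(chain) - 1)))
        nodes = [n for n in chain[k:] if n not in fixed]
        bcs.guide_nodes(nodes, normal)
    for tid in TRUNK_IDS:
        bcs.add_normal_pressure(mesh, f"distal_{tid}", pressure,
                                geom.trunks[tid].direction)
    return bcs


def solve_case(geom: PlexusGeometry, mesh: Mesh, case: LoadCase,
               scheme: str = "full_2x2", guided_fraction: float = 0.5):
    """Solve one load case on a meshed geometry."""
    mat = MaterialProperties(case.youngs_modulus, case.poisson_ratio)
    bcs = make_boundary_conditions(geom, mesh, case.applied_pressure,
                                   guided_fraction)
    return assemble_and_solve(mesh, mat, bcs, scheme)


def evaluate(geom: PlexusGeometry, mesh: Mesh, sol: Solution,
             stress: StressField, case_id: str, label: str,
             measure: str = "centroid") -> StudyResult:
    """Extract the reported quantities from one solve."""
    stresses = {rid: max_junction_stress(stress, mesh, rid, measure)
                for rid in ROOT_IDS}
    disps = {tid: distal_displacement(sol, mesh, tid) for tid in TRUNK_IDS}
    lengths = {tid: path_length(geom, tid) for tid in TRUNK_IDS}
    strains = {tid: engineering_strain(disps[tid], lengths[tid])
               for tid in TRUNK_IDS}
    return StudyResult(case_id, label, stresses, disps, strains, lengths,
                       equilibrium_residual=sol.equilibrium_residual)


def run_validation(config: PlexusConfig | None = None
                   ) -> tuple[StudyResult, StudyResult]:
    """Phase one: baseline anatomy under both load cases on one mesh."""
    cfg = config if config is not None else load_config()
    geom = cfg.build_geometry()
    mesh = generate_mesh(geom, cfg.mesh.h_max, cfg.mesh.h_min)
    results = []
    for cid in ("case1", "case2"):
        sol, stress = solve_case(geom, mesh, cfg.load_cases[cid],
                                 cfg.integration_scheme,
                                 cfg.guided_edge_fraction)
        results.append(evaluate(geom, mesh, sol, stress, cid, "baseline",
                                cfg.stress_measure))
    r1, r2 = results
    ratio = (cfg.load_cases["case2"].applied_pressure
             / cfg.load_cases["case1"].applied_pressure)
    for rid in ROOT_IDS:
        got = r2.root_stresses[rid] / r1.root_stresses[rid]
        if abs(got / ratio - 1.0) > _RATIO_TOL:
            raise PlexusError(
                f"linearity violated at {rid}: case2/case1 stress ratio "
                f"{got:.8f} vs pressure ratio {ratio:.8f}")
    return r1, r2


def run_angle_sweep(config: PlexusConfig | None = None,
                    case_id: str = "case1"
                    ) -> tuple[dict[float, StudyResult], dict[float, str]]:
    """Phase two: simultaneous perturbation of all root angles by each
    configured delta; returns (results keyed by delta, failures keyed by
    delta with the error message)."""
    cfg = config if config is not None else load_config()
    deltas = tuple(cfg.angle_deltas)
    if 0.0 not in deltas:
        raise ValueError("angle sweep requires the baseline delta 0")
    baseline_geom = cfg.build_geometry()
    case = cfg.load_cases[case_id]
    results: dict[float, StudyResult] = {}
    failures: dict[float, str] = {}
    for delta in sorted(deltas):
        try:
            geom = (baseline_geom if delta == 0.0 else
                    perturb_root_angles(baseline_geom, delta,
                                        cfg.max_angle_delta))
            mesh = generate_mesh(geom, cfg.mesh.h_max, cfg.mesh.h_min)
            sol, stress = solve_case(geom, mesh, case, cfg.integration_scheme,
                                     cfg.guided_edge_fraction)
            label = "baseline" if delta == 0.0 else f"delta{delta:+g}"
            results[delta] = evaluate(geom, mesh, sol, stress, case_id,
                                      label, cfg.stress_measure)
        except (GeometryInfeasibleError, MeshError) as exc:
            failures[delta] = str(exc)
    if 0.0 not in results:
        raise PlexusError(f"baseline run failed: {failures.get(0.0)}")
    base = results[0.0]
    for res in results.values():
        res.attach_baseline(base)   # delta 0 yields 0% everywhere
    return results, failures


def run_convergence(config: PlexusConfig | None = None,
                    factors: tuple[float, ...] = (1.0, 2.0),
                    case_id: str = "case1") -> list[dict]:
    """Uniform mesh refinement study at the configured size bounds;
    reports the C5 junction stress and its relative change per level."""
    cfg = config if config is not None else load_config()
    geom = cfg.build_geometry()
    case = cfg.load_cases[case_id]
    rows = []
    prev = None
    for fac in factors:
        h_max, h_min = cfg.mesh.h_max / fac, cfg.mesh.h_min / fac
        mesh = generate_mesh(geom, h_max, h_min)
        sol, stress = solve_case(geom, mesh, case, cfg.integration_scheme,
                                 cfg.guided_edge_fraction)
        val = max_junction_stress(stress, mesh, "C5", cfg.stress_measure)
        rows.append({
            "factor": fac, "h_max": h_max, "h_min": h_min,
            "n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements,
            "c5_stress_MPa": val,
            "rel_change": None if prev is None else abs(val - prev) / prev,
        })
        prev = val
    return rows


def write_validation_outputs(r1: StudyResult, r2: StudyResult,
                             outdir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write phase-one tables (per-root stresses; per-trunk lengths,
    displacements and strains) as CSV or JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "csv":
        import pandas as pd
        stresses = pd.concat([r1.stresses_frame(), r2.stresses_frame()])
        p = out / "validation_stresses.csv"
        stresses.to_csv(p)
        written.append(p)
        for r in (r1, r2):
            p = out / f"validation_trunks_{r.case_id}.csv"
            r.trunks_frame().to_csv(p, index=False)
            written.append(p)
    else:
        p = out / "validation.json"
        p.write_text(json.dumps({"case1": r1.to_dict(), "case2": r2.to_dict()},
                                indent=2) + "\n")
        written.append(p)
    return written


def write_sweep_outputs(results: dict[float, StudyResult],
                        failures: dict[float, str], outdir: str | Path,
                        fmt: str = "csv") -> list[Path]:
    """Write the phase-two angle-variation table as CSV or JSON."""
    from .postprocess import angle_sweep_frame
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "csv":
        p = out / "angle_sweep.csv"
        angle_sweep_frame(results).to_csv(p)
        written.append(p)
    else:
        doc = {str(d): r.to_dict() for d, r in sorted(results.items())}
        if failures:
            doc["failures"] = {str(d): m for d, m in failures.items()}
        p = out / "angle_sweep.json"
        p.write_text(json.dumps(doc, indent=2) + "\n")
        written.append(p)
    return written
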