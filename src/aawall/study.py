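"""Parametric wall-stress experiments: baselines, isolated sweeps, interactions.

One "case" is a full pipeline run (geometry -> mesh -> nonlinear solve ->
PWS/AWS within the aneurysmal sac).  Sweeps vary exactly one geometric or
mechanical parameter over its study grid with all others at the baseline
AAA values; the headline sensitivity statistic is the maximum percent change
in PWS relative to the baseline over the examined range.  Results are tidy
pandas tables (one row per case).  All computations are deterministic; a
case cache keyed by the full parameter signature guarantees the baseline is
identical across sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import constitutive as co
from . import geometry as geo
from .fe_solver import BoundaryConditions, SolverSettings, run_case
from .postprocess import sac_region, summarize, von_mises

__all__ = [
    "GEOMETRIC_SWEEPS", "MATERIAL_SWEEPS", "SweepSpec", "SweepResult",
    "StudyRunner", "percent_change_pws",
]

#: study grids for the seven sac parameters (baseline values included)
GEOMETRIC_SWEEPS: dict[str, list[float]] = {
    "axial_extent": [48.0, 64.0, 80.0, 96.0],
    "circ_extent": [90.0, 180.0, 270.0, 360.0],
    "max_diameter": [35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0],
    "location_z": [32.0, 48.0, 64.0],
    "sac_thickness": [0.75, 1.00, 1.25, 1.50, 1.75, 2.00],
    "tort_xz": [-1.175, -1.05, 1.00, 1.05, 1.175],
    "tort_yz": [-1.175, -1.05, 1.00, 1.05, 1.175],
}

#: study grids for the aneurysmal material parameters
MATERIAL_SWEEPS: dict[str, list[float]] = {
    "mu": [0.001, 0.004, 0.009, 0.013, 0.017, 0.040, 0.085, 0.100],
    "k1": [1.00, 1.50, 2.00, 2.74, 6.00, 15.00, 50.00],
    "k2": [0.001, 1.0, 30.0, 70.0, 119.6, 350.0, 500.0],
}

#: secondary-parameter levels for the diameter-interaction study
INTERACTION_LEVELS: dict[str, list[float]] = {
    "sac_thickness": [1.0, 1.5, 2.0],
    "axial_extent": [64.0, 96.0],
    "k1": [1.0, 2.74, 15.0, 50.0],
}

_GEOM_PARAMS = set(GEOMETRIC_SWEEPS)
_MAT_PARAMS = set(MATERIAL_SWEEPS)


@dataclass(frozen=True)
class SweepSpec:
    """One isolated parametric sweep around the baseline AAA."""

    parameter: str
    values: tuple[float, ...]
    target_edge: float = 2.6

    def __post_init__(self):
        if self.parameter not in _GEOM_PARAMS | _MAT_PARAMS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")


@dataclass
class SweepResult:
    parameter: str
    table: pd.DataFrame              # columns: value, PWS, AWS, n_elements, converged
    baseline_pws: float
    baseline_aws: float

    @property
    def max_percent_change_pws(self) -> float:
        return percent_change_pws(self)

    @property
    def max_percent_change_aws(self) -> float:
        ok = self.table.dropna(subset=["AWS"])
        return float((np.abs(ok["AWS"] - self.baseline_aws) / self.baseline_aws).max() * 100.0)


def percent_change_pws(result: SweepResult) -> float:
    """Maximum percent change of PWS over the sweep relative to the baseline."""
    if result.baseline_pws <= 0:
        raise ValueError("baseline PWS must be positive")
    ok = result.table.dropna(subset=["PWS"])
    return float((np.abs(ok["PWS"] - result.baseline_pws) / result.baseline_pws).max() * 100.0)


class StudyRunner:
    """Runs and caches pipeline cases at a fixed mesh resolution."""

    def __init__(self, target_edge: float = 2.6,
                 bc: BoundaryConditions | None = None,
                 settings: SolverSettings | None = None,
                 ref: geo.ReferentGeometryParameters | None = None,
                 resolution: tuple[int, int, int] | None = None,
                 keep_fields: bool = False, verbose: bool = False):
        self.target_edge = target_edge
        self.bc = bc or BoundaryConditions()
        self.settings = settings or SolverSettings()
        self.ref = ref or geo.ReferentGeometryParameters()
        self.resolution = resolution
        self.keep_fields = keep_fields
        self.verbose = verbose
        self._cache: dict[str, dict] = {}

    # -- case machinery ---------------------------------------------------
    def _key(self, aaa: geo.AAAParameters | None, mat: co.MaterialParameters) -> str:
        payload = {"aaa": asdict(aaa) if aaa else None, "mat": asdict(mat),
                   "edge": self.target_edge, "res": self.resolution, "bc": asdict(self.bc)}
        return json.dumps(payload, sort_keys=True)

    def case(self, aaa: geo.AAAParameters | None, mat: co.MaterialParameters) -> dict:
        """Solve one case (or fetch it from the cache); returns a summary dict."""
        key = self._key(aaa, mat)
        if key in self._cache:
            return self._cache[key]
        solid = geo.build_aaa(self.ref, aaa) if aaa is not None else geo.build_referent(self.ref)
        if self.verbose:
            print(f"  solving case aaa={aaa} mat=(mu={mat.mu}, k1={mat.k1}, k2={mat.k2})",
                  flush=True)
        mesh, sol = run_case(solid, mat, self.bc, self.settings,
                             target_edge=self.target_edge, resolution=self.resolution)
        region = sac_region(mesh, solid)
        summ = summarize(sol, mesh, region)
        vm_all = von_mises(sol.stress)
        rec = {
            "PWS": summ.PWS, "AWS": summ.AWS,
            "PWS_global": float(vm_all.max()),
            "n_elements": mesh.n_elements, "n_nodes": mesh.n_nodes,
            "converged": sol.converged,
            "wall_time_s": sol.provenance.get("wall_time_s"),
        }
        if self.keep_fields:
            rec["mesh"], rec["solution"], rec["solid"] = mesh, sol, solid
        self._cache[key] = rec
        return rec

    def _baseline_case(self) -> dict:
        return self.case(geo.BASELINE_AAA_GEOMETRY, co.BASELINE_AAA)

    # -- the experiments --------------------------------------------------
    def run_baselines(self) -> tuple[dict, dict]:
        """Referent-normal and baseline-AAA summaries at the working pressure.

        The referent summary carries both the sac-analogous-window PWS/AWS and
        the global PWS (which occurs at the aortic bifurcation).
        """
        referent = self.case(None, co.REFERENT_NORMAL)
        baseline = self._baseline_case()
        return referent, baseline

    def run_sweep(self, spec: SweepSpec) -> SweepResult:
        rows = []
        for v in spec.values:
            aaa, mat = self._perturbed(spec.parameter, v)
            try:
                rec = self.case(aaa, mat)
                rows.append({"value": v, "PWS": rec["PWS"], "AWS": rec["AWS"],
                             "n_elements": rec["n_elements"], "converged": True})
            except Exception as exc:  # per-case failures never abort a sweep
                rows.append({"value": v, "PWS": np.nan, "AWS": np.nan,
                             "n_elements": 0, "converged": False, "error": str(exc)})
        base = self._baseline_case()
        return SweepResult(parameter=spec.parameter, table=pd.DataFrame(rows),
                           baseline_pws=base["PWS"], baseline_aws=base["AWS"])

    def run_isolated_sweeps(self, which: Sequence[str] | None = None,
                            values: dict[str, Sequence[float]] | None = None
                            ) -> dict[str, SweepResult]:
        """One SweepResult per parameter, all others held at baseline."""
        grids = {**GEOMETRIC_SWEEPS, **MATERIAL_SWEEPS}
        which = list(which) if which is not None else list(grids)
        out = {}
        for name in which:
            vals = tuple((values or {}).get(name, grids[name]))
            out[name] = self.run_sweep(SweepSpec(name, vals, self.target_edge))
        return out

    def run_interaction_sweeps(self, diameters: Sequence[float] | None = None,
                               levels: dict[str, Sequence[float]] | None = None
                               ) -> pd.DataFrame:
        """PWS over the diameter grid crossed with secondary-parameter levels.

        Returns a tidy table with, per (diameter, secondary parameter), the
        PWS at each level and the spread (max - min) across levels.
        """
        diameters = list(diameters if diameters is not None
                         else GEOMETRIC_SWEEPS["max_diameter"])
        levels = {k: list(v) for k, v in (levels or INTERACTION_LEVELS).items()}
        rows = []
        for sec, lv in levels.items():
            for d in diameters:
                for v in lv:
                    aaa, mat = self._perturbed(sec, v)
                    aaa = replace(aaa, max_diameter=d)
                    try:
                        rec = self.case(aaa, mat)
                        rows.append({"secondary": sec, "diameter": d, "level": v,
                                     "PWS": rec["PWS"], "AWS": rec["AWS"]})
                    except Exception as exc:
                        rows.append({"secondary": sec, "diameter": d, "level": v,
                                     "PWS": np.nan, "AWS": np.nan, "error": str(exc)})
        df = pd.DataFrame(rows)
        spread = (df.groupby(["secondary", "diameter"])["PWS"]
                  .agg(lambda s: s.max() - s.min()).rename("PWS_spread").reset_index())
        return df.merge(spread, on=["secondary", "diameter"])

    def _perturbed(self, name: str, value: float):
        aaa = geo.BASELINE_AAA_GEOMETRY
        mat = co.BASELINE_AAA
        if name in _GEOM_PARAMS:
            aaa = replace(aaa, **{name: value})
        elif name in _MAT_PARAMS:
            mat = co.MaterialParameters(**{**{k: getattr(co.BASELINE_AAA, k)
                                              for k in ("mu", "k1", "k2", "phi")},
                                           name: value})
        else:
            raise ValueError(f"unknown parameter {name!r}")
        return aaa, mat

    # -- reporting --------------------------------------------------------
    def sensitivity_table(self, sweeps: dict[str, SweepResult]) -> pd.DataFrame:
        """Summary of max percent change in PWS/AWS per swept parameter."""
        rows = []
        for name, res in sweeps.items():
            rows.append({
                "parameter": name,
                "baseline_PWS": res.baseline_pws,
                "max_pct_change_PWS": res.max_percent_change_pws,
                "max_pct_change_AWS": res.max_percent_change_aws,
            })
        return pd.DataFrame(rows)
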