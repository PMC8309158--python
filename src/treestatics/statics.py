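"""High-level modelling interface: `TreeStatics(...).fit()` → results.

`TreeStatics` bundles a structural tree model with its loading
configuration; `fit()` discretizes the spans, assembles and solves every
requested load combination, and returns a `TreeStaticsResults` object
carrying displacement/stress tables, reactions, risk utilization ratios
and a text `summary()`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fem
from .loads import LoadConfig, WindSpec, build_cases, combine
from .model import TreeModel, load_model
from .sections import CircularSection, shell_risk_metrics

DEFAULT_STRENGTH_COMPRESSION = 20.0e6  # Pa, literature value for lime wood
DEFAULT_STRENGTH_TENSION = 20.0e6      # Pa, symmetric default


@dataclass
class TreeStatics:
    """Static structural model of a standing tree.

    Parameters
    ----------
    model : TreeModel
        Validated skeleton + sections + material + support.
    wind : WindSpec
        Reference velocity, air density, force coefficient and
        transparency-reduced crown area.
    foliage_mass : float
        Total crown foliage mass in kg (measured or allometric).
    foliage_beams : list of str, optional
        Beams carrying foliage weight and crown wind drag; defaults to
        all role=branch beams.
    combinations : tuple of str
        Which of C1 (self-weight), C2 (+wind x), C3 (+wind y) to solve.
    subdivisions : int
        Prismatic sub-elements per tapered span.
    exclusions : tuple of str
        Beam ids excluded from the stress ranking (abnormal geometry).
    """

    model: TreeModel
    wind: WindSpec
    foliage_mass: float
    foliage_beams: list[str] | None = None
    combinations: tuple[str, ...] = ("C1", "C2", "C3")
    subdivisions: int = 8
    exclusions: tuple[str, ...] = ()
    strength_compression: float = DEFAULT_STRENGTH_COMPRESSION
    strength_tension: float = DEFAULT_STRENGTH_TENSION

    @classmethod
    def from_files(cls, model_path, **kwargs) -> "TreeStatics":
        return cls(model=load_model(model_path), **kwargs)

    def load_config(self) -> LoadConfig:
        return LoadConfig(wind=self.wind, foliage_mass=self.foliage_mass,
                          foliage_beams=self.foliage_beams,
                          combinations=self.combinations)

    def fit(self) -> "TreeStaticsResults":
        mesh = fem.discretize(self.model, self.subdivisions)
        cases = build_cases(self.model, self.load_config())
        solutions = {}
        for name in self.combinations:
            combo = combine(name, cases)
            solutions[name] = fem.assemble_and_solve(mesh, combo)
        return TreeStaticsResults(model=self, mesh=mesh, cases=cases,
                                  solutions=solutions)


@dataclass
class TreeStaticsResults:
    """Solved displacements, stresses, reactions and risk ratios."""

    model: TreeStatics
    mesh: fem.ElementMesh
    cases: dict
    solutions: dict[str, fem.SolveResult]

    # -- tables ---------------------------------------------------------------

    def displacement_table(self) -> pd.DataFrame:
        """Per model node: ux, uy, uz (mm) for every combination."""
        rows = []
        for name, sol in self.solutions.items():
            for nid, idx in self.mesh.model_node_index.items():
                u = sol.displacements[idx]
                rows.append({"combination": name, "node": nid,
                             "ux_mm": u[0] * 1e3, "uy_mm": u[1] * 1e3,
                             "uz_mm": u[2] * 1e3,
                             "u_mm": float(np.linalg.norm(u[:3])) * 1e3})
        return pd.DataFrame(rows)

    def stress_table(self) -> pd.DataFrame:
        """Per recovery station: extreme-fiber stresses (MPa, tension +)."""
        rows = []
        for name, sol in self.solutions.items():
            for st in sol.stations:
                rows.append({"combination": name, "beam": st.beam_id,
                             "span": st.span_index, "s": st.s,
                             "sigma_t_MPa": st.sigma_tension / 1e6,
                             "sigma_c_MPa": st.sigma_compression / 1e6})
        return pd.DataFrame(rows)

    def reaction_table(self) -> pd.DataFrame:
        rows = []
        for name, sol in self.solutions.items():
            r = sol.reactions
            rows.append({"combination": name,
                         "Rx_kN": r[0] / 1e3, "Ry_kN": r[1] / 1e3,
                         "Rz_kN": r[2] / 1e3, "Mx_kNm": r[3] / 1e3,
                         "My_kNm": r[4] / 1e3, "Mz_kNm": r[5] / 1e3,
                         "equilibrium_residual": sol.equilibrium_residual})
        return pd.DataFrame(rows)

    # -- headline summaries ---------------------------------------------------

    def combination_summary(self) -> dict:
        return {name: fem.summarize(sol, list(self.model.exclusions))
                for name, sol in self.solutions.items()}

    def risk_flags(self, t_over_r_threshold: float = 0.3) -> pd.DataFrame:
        """Utilization ratios |σ|/strength plus shell-wall t/R flags.

        Never asserts safety — only reports ratios and threshold
        exceedances per combination / hollow section.
        """
        rows = []
        for name, summ in self.combination_summary().items():
            ut = summ["max_tension_MPa"] * 1e6 / self.model.strength_tension
            uc = abs(summ["max_compression_MPa"]) * 1e6 / self.model.strength_compression
            rows.append({"combination": name, "check": "tension",
                         "value_MPa": summ["max_tension_MPa"],
                         "utilization": ut, "flag": ut >= 1.0,
                         "location": str(summ["max_tension_location"])})
            rows.append({"combination": name, "check": "compression",
                         "value_MPa": summ["max_compression_MPa"],
                         "utilization": uc, "flag": uc >= 1.0,
                         "location": str(summ["max_compression_location"])})
        seen = set()
        for beam in self.model.model.beams:
            for i, span in enumerate(beam.spans):
                for sec in (span.section_start, span.section_end):
                    if isinstance(sec, CircularSection) and sec.r > 0 and id(sec) not in seen:
                        seen.add(id(sec))
                        m = shell_risk_metrics(sec, t_over_r_threshold)
                        rows.append({"combination": "-", "check": "t_over_R",
                                     "value_MPa": np.nan,
                                     "utilization": m["t_over_R"],
                                     "flag": m["flag"],
                                     "location": f"{beam.id} span {i}"})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        m = self.model
        lines = ["Tree static analysis", "=" * 60]
        counts = m.model.validate()
        lines.append(f"model: {counts['beams']} beams, {counts['nodes']} nodes, "
                     f"{counts['spans']} spans, {counts['sections']} sections")
        mat = m.model.material
        lines.append(f"material: rho={mat.density:.0f} kg/m3, "
                     f"E={mat.E/1e9:.2f} GPa, G={mat.G/1e9:.3f} GPa")
        lines.append(f"wind: v={m.wind.velocity:g} m/s, "
                     f"A_reduced={m.wind.exposed_area} m2; "
                     f"foliage mass={m.foliage_mass:g} kg; "
                     f"subdivisions={m.subdivisions}")
        if m.exclusions:
            lines.append(f"excluded beams: {', '.join(m.exclusions)}")
        lines.append("-" * 60)
        for name, summ in self.combination_summary().items():
            lines.append(
                f"{name}: max |u| = {summ['max_displacement_mm']:.1f} mm at "
                f"{summ['max_displacement_node']}; "
                f"max horiz = {summ['max_horizontal_mm']:.1f} mm at "
                f"{summ['max_horizontal_node']}")
            lines.append(
                f"    sigma_t = {summ['max_tension_MPa']:+.2f} MPa at "
                f"{summ['max_tension_location']}; "
                f"sigma_c = {summ['max_compression_MPa']:+.2f} MPa at "
                f"{summ['max_compression_location']} "
                f"(residual {summ['equilibrium_residual']:.1e})")
        return "\n".join(lines)

    # -- export ---------------------------------------------------------------

    def to_directory(self, outdir) -> dict:
        """Write CSV tables + JSON summary; return the summary dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.displacement_table().to_csv(outdir / "displacements.csv", index=False)
        self.stress_table().to_csv(outdir / "stresses.csv", index=False)
        self.reaction_table().to_csv(outdir / "reactions.csv", index=False)
        self.risk_flags().to_csv(outdir / "risk_flags.csv", index=False)
        summary = {
            "config": {
                "wind_velocity": self.model.wind.velocity,
                "air_density": self.model.wind.air_density,
                "force_coefficient": self.model.wind.force_coefficient,
                "exposed_area": self.model.wind.exposed_area,
                "foliage_mass": self.model.foliage_mass,
                "foliage_beams": self.model.foliage_beams,
                "subdivisions": self.model.subdivisions,
                "exclusions": list(self.model.exclusions),
                "strength_compression_MPa": self.model.strength_compression / 1e6,
                "strength_tension_MPa": self.model.strength_tension / 1e6,
            },
            "combinations": self.combination_summary(),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                        sort_keys=True))
        return summary


def run_pipeline(model: TreeModel, wind: WindSpec, foliage_mass: float,
                 outdir=None, **kwargs) -> TreeStaticsResults:
    """One-call pipeline: build the model object, fit, optionally export."""
    ts = TreeStatics(model=model, wind=wind, foliage_mass=foliage_mass, **kwargs)
    results = ts.fit()
    if outdir is not None:
        results.to_directory(outdir)
    return results
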