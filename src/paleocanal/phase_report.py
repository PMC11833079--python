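"""Scenario comparison: how the canal phase shifts the effective constants.

Percent changes are reported *reduction-positive*: ``change(X) =
(X_solid - X_phase) / X_solid * 100`` for moduli and density, so a softer
phase gives a positive number; a Poisson ratio that rises under a softer
phase therefore reads negative and is additionally echoed as a
"+x % increase".  The convention is stated in every output header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microfe import EngineeringConstants

__all__ = ["PhaseComparison", "compare_phases", "compare_scenarios"]

_MODULI = ("E_r", "E_t", "E_z", "G_rt", "G_tz", "G_rz")
_POISSON = ("nu_rt", "nu_rz", "nu_tz")
_ALL = _MODULI + _POISSON + ("mean_density",)


@dataclass
class PhaseComparison:
    """Per-constant values for the three scenarios plus percent changes."""

    values: dict[str, dict[str, float]]  # constant -> scenario -> value
    changes: dict[str, dict[str, float]]  # constant -> scenario -> % reduction vs solid
    aggregates: dict[str, dict[str, float]]  # "E"/"G"/"nu" -> scenario -> mean % change

    def to_table(self) -> dict:
        """Rows keyed by scenario with unit-annotated columns (reduction-positive %)."""
        out = {}
        for scen in ("solid", "liquid", "gas"):
            row = {}
            for name in _ALL:
                row[f"{name} [GPa]" if name in _MODULI else f"{name}"] = self.values[name][scen]
                row[f"{name} reduction vs solid [%]"] = self.changes[name][scen]
            for agg in ("E", "G", "nu"):
                row[f"mean {agg} reduction vs solid [%]"] = self.aggregates[agg][scen]
            out[scen] = row
        return out


def compare_phases(
    solid: EngineeringConstants,
    liquid: EngineeringConstants,
    gas: EngineeringConstants,
) -> PhaseComparison:
    """Build the phase-comparison table from three constant sets.

    All three sets must come from the same geometry (checked by hash).
    Aggregates are unweighted means over the three Young's moduli, the
    three shear moduli, and the three Poisson ratios.
    """
    sets = {"solid": solid, "liquid": liquid, "gas": gas}
    hashes = {s.geometry_hash for s in sets.values() if s.geometry_hash}
    if len(hashes) > 1:
        raise ValueError(f"constant sets come from different geometries: {sorted(hashes)}")
    values: dict[str, dict[str, float]] = {}
    changes: dict[str, dict[str, float]] = {}
    for name in _ALL:
        values[name] = {scen: float(getattr(ec, name)) for scen, ec in sets.items()}
        ref = values[name]["solid"]
        changes[name] = {
            scen: 100.0 * (ref - v) / ref if ref != 0 else float("nan")
            for scen, v in values[name].items()
        }
    aggregates = {
        "E": {scen: float(np.mean([changes[n][scen] for n in ("E_r", "E_t", "E_z")])) for scen in sets},
        "G": {scen: float(np.mean([changes[n][scen] for n in ("G_rt", "G_tz", "G_rz")])) for scen in sets},
        "nu": {scen: float(np.mean([changes[n][scen] for n in _POISSON])) for scen in sets},
    }
    return PhaseComparison(values=values, changes=changes, aggregates=aggregates)


def compare_scenarios(label, spec, strain: float = 0.02, tol: float = 1e-6, **kwargs) -> PhaseComparison:
    """Run all three canal-phase scenarios on one geometry and compare.

    Scenarios are solved in the order solid, liquid, gas, each warm-started
    from the previous scenario's displacement fields.
    """
    from .microfe import homogenize

    fields = None
    results = {}
    for scen in ("solid", "liquid", "gas"):
        results[scen], fields = homogenize(
            label, spec, scen, strain=strain, tol=tol,
            warm_start=fields, return_fields=True, **kwargs,
        )
    return compare_phases(results["solid"], results["liquid"], results["gas"])
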