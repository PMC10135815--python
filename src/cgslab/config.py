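"""YAML run-configuration schema.

A single YAML file describes either one run or a grid campaign:

.. code-block:: yaml

    preset: desk                 # desk | medium | production
    system: PLD                  # segment name or raw sequence
    mass_scale: 1.2
    insertion_mode: none         # none | tail10 | head5tail5
    charge_mode: no_charge       # no_charge | salt_10mM
    temperature: 2.0             # T0 units
    seed: 1
    forcefield:                  # optional overrides of the preset's values
      eps: 0.001
      kappa: 0.32
    simulation:                  # optional overrides (dt_ps, duration_tau, ...)
      duration_tau: 100.0
    grid:                        # optional: lists turn the run into a grid
      mass_scales: [1.0, 1.2]
      temperatures: [1.0, 2.0, 3.0, 4.0]
      seeds: [1, 2, 3]

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .grid import ExperimentGrid
from .potentials import ForceFieldParams
from .simulator import PRESETS, Preset, SimulationConfig

_TOP_KEYS = {"preset", "system", "mass_scale", "insertion_mode",
             "charge_mode", "temperature", "seed", "forcefield",
             "simulation", "grid", "n_chains", "chain_length"}


def _override(obj, section: dict, what: str):
    valid = {f.name for f in fields(obj)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return replace(obj, **section)


def load_config(path_or_text):
    """Parse a YAML run config into (Preset, SimulationConfig, cell dict,
    optional ExperimentGrid)."""
    text = (Path(path_or_text).read_text()
            if isinstance(path_or_text, (str, Path))
            and "\n" not in str(path_or_text)
            and Path(path_or_text).exists()
            else str(path_or_text))
    raw = yaml.safe_load(text) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    preset = PRESETS[raw.get("preset", "desk")]
    ff = _override(preset.forcefield, raw.get("forcefield", {}),
                   "forcefield")
    sim = _override(preset.config, raw.get("simulation", {}), "simulation")
    sim = replace(
        sim,
        temperature=float(raw.get("temperature", sim.temperature)),
        seed=int(raw.get("seed", sim.seed)),
        charge_mode=raw.get("charge_mode", sim.charge_mode),
    )
    preset = Preset(name=preset.name, n_chains=raw.get("n_chains",
                                                       preset.n_chains),
                    chain_length=preset.chain_length, forcefield=ff,
                    config=sim, box=preset.box,
                    boundary_nm=preset.boundary_nm,
                    analysis_fraction=preset.analysis_fraction)

    cell = {
        "system": raw.get("system", "PLD"),
        "mass_scale": float(raw.get("mass_scale", 1.0)),
        "insertion_mode": raw.get("insertion_mode", "none"),
        "charge_mode": sim.charge_mode,
        "temperature": sim.temperature,
        "seed": sim.seed,
    }

    grid = None
    if "grid" in raw:
        g = raw["grid"]
        grid = ExperimentGrid(
            systems=tuple(g.get("systems", (cell["system"],))),
            mass_scales=tuple(g.get("mass_scales", (cell["mass_scale"],))),
            insertion_modes=tuple(g.get("insertion_modes",
                                        (cell["insertion_mode"],))),
            charge_modes=tuple(g.get("charge_modes",
                                     (cell["charge_mode"],))),
            temperatures=tuple(g.get("temperatures",
                                     (cell["temperature"],))),
            seeds=tuple(g.get("seeds", (cell["seed"],))),
            preset=raw.get("preset", "desk"),
            n_chains=raw.get("n_chains"),
            chain_length=raw.get("chain_length"),
        )
    return preset, sim, cell, grid
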