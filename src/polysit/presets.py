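"""Ready-made scenario presets matching the package's standard figure
setups (bifurcation diagram, transient ODE runs, heatmaps, ABM sweeps).

Each preset is a plain dict with ``parameters`` / ``release`` /
``simulation`` sections that the CLI can write as a config file and
feed back to the matching subcommand.
"""

from __future__ import annotations

from typing import Any

from .parameters import default_suzukii_parameters

__all__ = ["PRESETS", "make_preset"]


def _base() -> dict[str, Any]:
    return {"parameters": default_suzukii_parameters().to_dict()}


def _first_params() -> dict[str, Any]:
    p = default_suzukii_parameters().replace(tau_F=0.0, tau_I=0.0)
    return p.to_dict()


def make_preset(name: str) -> dict[str, Any]:
    name = name.lower()
    if name == "fig2":  # bifurcation diagram, First vs Last
        out = _base()
        out["simulation"] = {
            "command": "bifurcation",
            "sigma_min": 0.0, "sigma_max": 600_000.0, "sigma_steps": 121,
            "variants": {"first": {"tau_F": 0.0, "tau_I": 0.0}, "last": {}},
        }
        return out
    if name in ("fig4a", "fig4b"):  # transient ODE runs, three release rates
        high = name == "fig4a"
        out = _base()
        out["simulation"] = {
            "command": "ode-simulate",
            "model": "reduced",
            "init": {"L": 30_000, "M": 100_000, "F_I": 0, "F_F": 100_000} if high
            else {"L": 100, "M": 300, "F_I": 0, "F_F": 300},
            "sigmas": [0, 300_000, 450_000, 600_000],
            "horizon": 3000,
            "variants": {"first": {"tau_F": 0.0, "tau_I": 0.0}, "last": {}},
        }
        return out
    if name == "fig5":  # time × σ transient-difference heatmap
        out = _base()
        out["simulation"] = {
            "command": "transient-heatmap",
            "sigma_min": 0.0, "sigma_max": 600_000.0, "sigma_steps": 61,
            "horizon": 3000, "n_times": 301,
            "init": {"L": 30_000, "M": 100_000, "F_I": 0, "F_F": 100_000},
        }
        return out
    if name in ("fig6a", "fig6b"):  # eradication-threshold heatmaps
        out = _base()
        if name == "fig6a":
            axes = {"axis1": {"name": "tau_F", "min": 0.0, "max": 0.3, "steps": 100},
                    "axis2": {"name": "tau_I", "min": 0.0, "max": 0.3, "steps": 100}}
        else:
            axes = {"axis1": {"name": "eta", "min": 0.05, "max": 1.0, "steps": 100},
                    "axis2": {"name": "tau_I", "min": 0.0, "max": 0.3, "steps": 100}}
        out["simulation"] = {"command": "threshold-heatmap", "cap": 1_000_000.0, **axes}
        return out
    if name == "fig7":  # ABM sweep, three release rates, all six scenarios
        out = _base()
        out["simulation"] = {
            "command": "abm-sweep",
            "scenarios": ["first", "last", "mixed", "preference_w", "preference_i", "preference_s"],
            "sigmas": [10_000, 15_000, 20_000],
            "wild_males": 1000, "females": 1000, "larvae": 0,
            "horizon": 100, "n_replicates": 100, "seed": 0,
        }
        return out
    if name == "fig8":  # ABM sweep over the full release range
        out = make_preset("fig7")
        out["simulation"]["sigmas"] = [10_000, 15_000, 20_000, 30_000, 40_000, 50_000, 60_000]
        return out
    raise KeyError(f"unknown preset {name!r}")


PRESETS = ("fig2", "fig4a", "fig4b", "fig5", "fig6a", "fig6b", "fig7", "fig8")
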