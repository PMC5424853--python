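"""Loaders for the bundled model-parameter fixtures.

The YAML files under ``survcea/fixtures`` transcribe the published
regression results of the case study: the partitioned-survival fits (PFS
Weibull, observed-period OS exponential, FC tail Weibull, observed-period
OS hazard ratio), the per-transition Gompertz models of the semi-Markov
multi-state analysis, and the manufacturer's Markov-cohort transition
rules.  Every printed constant used by the reproduction pipelines lives in
these files, never in code.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

from .hazard_models import ParametricHazardModel
from .multistate_semimarkov import T12, T13, T23, MultiStateSpec

_TRANS_KEYS = {"pf_to_prog": T12, "pf_to_death": T13, "prog_to_death": T23}


def _load_yaml(name: str) -> dict[str, Any]:
    ref = resources.files("survcea") / "fixtures" / name
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_yaml_model(block: dict[str, Any]) -> ParametricHazardModel:
    """Build a hazard model from a {family, params, coefficients, ...} block."""
    return ParametricHazardModel(
        family=block["family"],
        params=dict(block["params"]),
        coefficients=dict(block.get("coefficients", {})),
        standard_errors=(
            dict(block["standard_errors"]) if block.get("standard_errors") else None
        ),
    )


def load_partitioned_params(path=None) -> dict[str, Any]:
    """Partitioned-survival parameter set (bundled fixture by default)."""
    raw = _load_yaml("partitioned.yaml") if path is None else yaml.safe_load(
        open(path)
    )
    return {
        "pfs": load_yaml_model(raw["pfs"]),
        "os_observed": load_yaml_model(raw["os_observed"]),
        "os_tail": load_yaml_model(raw["os_tail"]),
        "observed_boundary": float(raw["observed_boundary"]),
        "os_observed_hr": float(raw["os_observed_hr"]),
        "horizon": float(raw.get("horizon", 15.0)),
    }


def load_multistate_spec(
    path=None, use_printed_hr: bool = True
) -> tuple[MultiStateSpec, dict[tuple[int, int], float]]:
    """Baseline (control-arm) multi-state spec and the treatment HR map.

    ``use_printed_hr=True`` takes the published hazard ratios; otherwise the
    HRs are recomputed as exp(coefficient) (the source prints both, and for
    one transition they disagree slightly).
    """
    raw = _load_yaml("multistate.yaml") if path is None else yaml.safe_load(open(path))
    models, clocks, hrs = {}, {}, {}
    for name, trans in _TRANS_KEYS.items():
        block = raw["transitions"][name]
        models[trans] = ParametricHazardModel(
            family=block["family"], params=dict(block["params"])
        )
        clocks[trans] = block["clock"]
        if use_printed_hr:
            hrs[trans] = float(block["hr_printed"])
        else:
            import numpy as np

            hrs[trans] = float(np.exp(block["treatment_coefficient"]))
    spec = MultiStateSpec(models=models, clocks=clocks)
    return spec, hrs


def load_markov_rules(path=None) -> dict[str, Any]:
    """Manufacturer-style Markov cohort transition rules (raw dict)."""
    raw = _load_yaml("markov.yaml") if path is None else yaml.safe_load(open(path))
    raw = dict(raw)
    raw["pfs_model"] = load_yaml_model(raw["pfs_model"])
    return raw
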