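"""YAML/JSON (de)serialization of task configurations.

A task config mirrors the model types::

    mixture:
      drifts: [0.20, 0.0]        # or an explicit support/prior pair
      weights: [0.5, 0.5]
      p_plus: 0.5
    rewards:
      R_C: 1.0
      R_I: 0.0
      D_C: 150
      D_I: 150                   # or D_p; omitted D_I defaults to D_C + D_p
      pass_delay: null
    t_max: 70
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .mdp import DriftMixture, RewardConfig, TaskModel

__all__ = [
    "mixture_from_dict",
    "mixture_to_dict",
    "task_from_dict",
    "task_to_dict",
    "load_task",
    "dump_task",
    "config_hash",
]


def mixture_from_dict(d: Mapping[str, Any]) -> DriftMixture:
    if "support" in d:
        return DriftMixture(
            tuple(float(u) for u in d["support"]),
            tuple(float(w) for w in d["prior"]),
            tuple(bool(e) for e in d.get("easy", ())),
        )
    return DriftMixture.from_drifts(
        d["drifts"],
        d.get("weights"),
        p_plus=float(d.get("p_plus", 0.5)),
        easy_drifts=d.get("easy_drifts"),
    )


def mixture_to_dict(m: DriftMixture) -> dict[str, Any]:
    return {
        "support": [float(u) for u in m.support],
        "prior": [float(w) for w in m.prior],
        "easy": [bool(e) for e in m.easy],
    }


def task_from_dict(d: Mapping[str, Any]) -> TaskModel:
    rw = d.get("rewards", {})
    return TaskModel(
        mixture=mixture_from_dict(d["mixture"]),
        rewards=RewardConfig(
            R_C=float(rw.get("R_C", 1.0)),
            R_I=float(rw.get("R_I", 0.0)),
            D_C=float(rw.get("D_C", 150.0)),
            D_I=None if rw.get("D_I") is None else float(rw["D_I"]),
            D_p=None if rw.get("D_p") is None else float(rw["D_p"]),
            pass_delay=(
                None if rw.get("pass_delay") is None else float(rw["pass_delay"])
            ),
        ),
        t_max=int(d.get("t_max", 70)),
    )


def task_to_dict(model: TaskModel) -> dict[str, Any]:
    rw = model.rewards
    return {
        "mixture": mixture_to_dict(model.mixture),
        "rewards": {
            "R_C": rw.R_C,
            "R_I": rw.R_I,
            "D_C": rw.D_C,
            "D_I": rw.D_I,
            "D_p": rw.D_p,
            "pass_delay": rw.pass_delay,
        },
        "t_max": model.t_max,
        "actions": list(model.actions),
    }


def load_task(path: str | Path) -> TaskModel:
    """Load a task config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return task_from_dict(data)


def dump_task(model: TaskModel, path: str | Path) -> None:
    path = Path(path)
    data = task_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def config_hash(model: TaskModel) -> str:
    """Stable hash of a resolved task config (for run logs)."""
    blob = json.dumps(task_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
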