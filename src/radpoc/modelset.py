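"""Model-set containers and structured config I/O (YAML/JSON).

A model set bundles the fitted risk models, the per-cancer-group MMI
weight trees, optional conservative max-ERR groups, and an optional
smoking prevalence table, and round-trips through a YAML/JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .mmi import WeightTree
from .models import (
    BaselineSpec,
    DoseResponseSpec,
    ModifierSpec,
    RiskModel,
    ScreeningSpec,
)

__all__ = ["ModelGroup", "ModelSet", "load_model_set", "save_model_set"]


@dataclass
class ModelGroup:
    """One cancer group: disease class, MMI tree, optional max-ERR group."""

    name: str
    disease_class: str
    tree: WeightTree
    max_group: list = field(default_factory=list)


@dataclass
class ModelSet:
    """Risk models plus per-group MMI configuration."""

    id: str
    models: dict = field(default_factory=dict)  # id -> RiskModel
    groups: dict = field(default_factory=dict)  # name -> ModelGroup
    smoking_prevalence: dict | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for group in self.groups.values():
            for mid in group.tree.all_model_ids():
                if mid not in self.models:
                    raise ConfigurationError(
                        f"group {group.name!r} references unknown model {mid!r}"
                    )
                if self.models[mid].disease_class != group.disease_class:
                    raise ConfigurationError(
                        f"model {mid!r} disease class does not match group {group.name!r}"
                    )
            for mid in group.max_group:
                if mid not in self.models:
                    raise ConfigurationError(
                        f"max-ERR group of {group.name!r} references unknown model {mid!r}"
                    )
                if self.models[mid].kind != "ERR":
                    raise ConfigurationError(
                        "max-ERR groups may contain only ERR-type models"
                    )
        for model in self.models.values():
            if model.twin_id is not None and model.twin_id not in self.models:
                raise ConfigurationError(
                    f"model {model.id!r} declares missing twin {model.twin_id!r}"
                )


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

def _model_to_dict(m: RiskModel) -> dict:
    d: dict = {
        "id": m.id,
        "kind": m.kind,
        "disease_class": m.disease_class,
        "dose_response": {"form": m.dose_response.form, "knot_dose": m.dose_response.knot_dose},
        "modifiers": {
            "sex": m.modifier_spec.sex,
            "sex_convention": m.modifier_spec.sex_convention,
            "attained_age": m.modifier_spec.attained_age,
            "age_centre": m.modifier_spec.age_centre,
            "age_at_exposure": m.modifier_spec.age_at_exposure,
            "exposure_centre": m.modifier_spec.exposure_centre,
            "smoking": m.modifier_spec.smoking,
        },
        "params": {k: float(v) for k, v in m.params.items()},
        "covariance": np.asarray(m.covariance).tolist(),
        "aic": float(m.aic),
        "lss_cohort_flags": m.lss_cohort_flags,
    }
    if m.baseline_spec is not None:
        d["baseline"] = {
            "age_centre": m.baseline_spec.age_centre,
            "byr_centre": m.baseline_spec.byr_centre,
            "g_average": m.baseline_spec.g_average,
        }
    if m.screening_spec is not None:
        d["screening"] = {
            "breaks": list(m.screening_spec.breaks),
            "factors": list(m.screening_spec.factors),
        }
    if m.twin_id is not None:
        d["twin_id"] = m.twin_id
    return d


def _model_from_dict(d: dict) -> RiskModel:
    mod = d.get("modifiers", {})
    baseline = None
    if "baseline" in d:
        b = d["baseline"]
        baseline = BaselineSpec(
            age_centre=b.get("age_centre", 70.0),
            byr_centre=b.get("byr_centre", 1930.0),
            g_average=b.get("g_average", 1.0),
        )
    screening = None
    if "screening" in d:
        s = d["screening"]
        screening = ScreeningSpec(breaks=tuple(s["breaks"]), factors=tuple(s["factors"]))
    dr = d.get("dose_response", {})
    return RiskModel(
        id=d["id"],
        kind=d["kind"],
        disease_class=d["disease_class"],
        dose_response=DoseResponseSpec(
            form=dr.get("form", "linear"), knot_dose=dr.get("knot_dose", 0.7)
        ),
        modifier_spec=ModifierSpec(
            sex=mod.get("sex", False),
            sex_convention=mod.get("sex_convention", "loglinear"),
            attained_age=mod.get("attained_age", False),
            age_centre=mod.get("age_centre", 70.0),
            age_at_exposure=mod.get("age_at_exposure", False),
            exposure_centre=mod.get("exposure_centre", 30.0),
            smoking=mod.get("smoking", False),
        ),
        baseline_spec=baseline,
        screening_spec=screening,
        params=dict(d.get("params", {})),
        covariance=np.asarray(d["covariance"], dtype=float) if "covariance" in d else None,
        aic=float(d.get("aic", 0.0)),
        twin_id=d.get("twin_id"),
        lss_cohort_flags=bool(d.get("lss_cohort_flags", False)),
    )


def _tree_to_dict(t: WeightTree) -> dict:
    if t.is_leaf:
        out: dict = {"models": list(t.model_ids)}
        if t.aics is not None:
            out["aics"] = [float(a) for a in t.aics]
        if t.leaf_weights is not None:
            out["weights"] = [float(w) for w in t.leaf_weights]
        return out
    return {
        "branches": [
            {"weight": float(w), "node": _tree_to_dict(child)} for w, child in t.branches
        ]
    }


def _tree_from_dict(d: dict) -> WeightTree:
    if "branches" in d:
        return WeightTree(
            branches=[(b["weight"], _tree_from_dict(b["node"])) for b in d["branches"]]
        )
    return WeightTree(
        model_ids=list(d["models"]),
        aics=d.get("aics"),
        leaf_weights=d.get("weights"),
    )


def model_set_to_dict(ms: ModelSet) -> dict:
    return {
        "id": ms.id,
        "models": [_model_to_dict(m) for m in ms.models.values()],
        "groups": {
            name: {
                "disease_class": g.disease_class,
                "tree": _tree_to_dict(g.tree),
                **({"max_group": list(g.max_group)} if g.max_group else {}),
            }
            for name, g in ms.groups.items()
        },
        **(
            {"smoking_prevalence": ms.smoking_prevalence}
            if ms.smoking_prevalence is not None
            else {}
        ),
    }


def model_set_from_dict(d: dict) -> ModelSet:
    models = {m["id"]: _model_from_dict(m) for m in d.get("models", [])}
    groups = {
        name: ModelGroup(
            name=name,
            disease_class=g["disease_class"],
            tree=_tree_from_dict(g["tree"]),
            max_group=list(g.get("max_group", [])),
        )
        for name, g in d.get("groups", {}).items()
    }
    return ModelSet(
        id=d.get("id", "unnamed"),
        models=models,
        groups=groups,
        smoking_prevalence=d.get("smoking_prevalence"),
    )


def load_model_set(path) -> ModelSet:
    """Read a model set from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_set_from_dict(data)


def save_model_set(ms: ModelSet, path) -> None:
    """Write a model set to YAML (or JSON if the path ends in .json)."""
    path = Path(path)
    data = model_set_to_dict(ms)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
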