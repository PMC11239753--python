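"""Configuration parsing: a YAML document describing a full calculation.

The document mirrors the package's specification objects section by section
(``design``, ``mean_model``, ``correlation``, ``variance``, ``contrasts``,
``plan``).  Parsing is strict — unknown keys are rejected and every scientific
parameter (theta, scaling constants, alpha levels) must be explicit — so a
power calculation is auditable from its config alone.  Validation problems
are aggregated and reported together, each naming the offending key.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .covariance import CorrelationSpec, VarianceSpec
from .design import DesignLayout, make_standard_swd
from .meanmodel import MeanModelSpec
from .power import ContrastSpec, MultiplicityPlan

__all__ = ["Bundle", "ConfigError", "parse_config", "parse_mapping", "serialize", "load_example"]


class ConfigError(ValueError):
    """One or more configuration problems; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class Bundle:
    """Everything needed to run a power or sample-size calculation."""

    layout: DesignLayout
    mean_model: MeanModelSpec
    correlation: CorrelationSpec
    variance: VarianceSpec
    contrasts: tuple[ContrastSpec, ...]
    plan: MultiplicityPlan
    il_split: float = 0.5
    n_max: int = 1000


_SECTION_KEYS = {
    "design": {"n_periods", "n_sequences", "clusters_per_sequence", "cohort_size",
               "il_split", "cohort_type"},
    "mean_model": {"effect_model", "time_trend", "link", "theta", "scaling", "poly_degree"},
    "correlation": {"family", "within_period", "inter_period", "within_individual",
                    "decay_inter_period"},
    "variance": {"family", "dispersion"},
    "plan": {"family_alpha", "power_goal", "n_max"},
}
_CONTRAST_KEYS = {"label", "effects", "L", "ell", "alpha", "in_goal"}
_EFFECT_NAMES = ("il", "cl", "interaction")


def _check_keys(section: str, mapping: dict, allowed: set[str], errors: list[str]) -> None:
    for key in mapping:
        if key not in allowed:
            errors.append(f"{section}: unknown key {key!r} (allowed: {sorted(allowed)})")


def _require(mapping: dict, section: str, key: str, errors: list[str]) -> Any:
    if key not in mapping:
        errors.append(f"{section}: missing required key {key!r}")
        return None
    return mapping[key]


def parse_mapping(doc: dict) -> Bundle:
    """Validate a parsed YAML mapping into a :class:`Bundle`."""
    errors: list[str] = []
    if not isinstance(doc, dict):
        raise ConfigError(["document must be a mapping of sections"])
    unknown_sections = set(doc) - set(_SECTION_KEYS) - {"contrasts"}
    for s in sorted(unknown_sections):
        errors.append(f"unknown section {s!r}")

    sections = {}
    for name in ("design", "mean_model", "correlation", "variance"):
        sec = doc.get(name)
        if sec is None:
            errors.append(f"missing section {name!r}")
            sec = {}
        elif not isinstance(sec, dict):
            errors.append(f"section {name!r} must be a mapping")
            sec = {}
        else:
            _check_keys(name, sec, _SECTION_KEYS[name], errors)
        sections[name] = sec
    plan_sec = doc.get("plan", {}) or {}
    _check_keys("plan", plan_sec, _SECTION_KEYS["plan"], errors)

    des = sections["design"]
    n_periods = _require(des, "design", "n_periods", errors)
    n_sequences = _require(des, "design", "n_sequences", errors)
    clusters = _require(des, "design", "clusters_per_sequence", errors)
    cohort = _require(des, "design", "cohort_size", errors)
    il_split = des.get("il_split", 0.5)
    cohort_type = des.get("cohort_type", "closed_cohort")

    mm = sections["mean_model"]
    effect_model = _require(mm, "mean_model", "effect_model", errors)
    time_trend = _require(mm, "mean_model", "time_trend", errors)
    link = _require(mm, "mean_model", "link", errors)
    theta = _require(mm, "mean_model", "theta", errors)
    scaling = mm.get("scaling", [1.0, 1.0, 1.0])
    if effect_model == "incremental" and "scaling" not in mm:
        errors.append("mean_model: incremental model requires explicit 'scaling' constants")

    co = sections["correlation"]
    family = _require(co, "correlation", "family", errors)
    alpha_triple = (
        co.get("within_period", 0.0),
        co.get("inter_period", 0.0),
        co.get("within_individual", 0.0),
    )
    if family in ("block_exchangeable", "block_autoregressive"):
        for key in ("within_period", "inter_period", "within_individual"):
            if key not in co:
                errors.append(f"correlation: missing required key {key!r} for family {family!r}")

    va = sections["variance"]
    v_family = _require(va, "variance", "family", errors)
    dispersion = _require(va, "variance", "dispersion", errors)

    raw_contrasts = doc.get("contrasts")
    if not raw_contrasts:
        errors.append("missing section 'contrasts' (need at least one hypothesis)")
        raw_contrasts = []

    if errors:
        raise ConfigError(errors)

    layout = make_standard_swd(
        int(n_periods), int(n_sequences), clusters, cohort, float(il_split), cohort_type
    )
    mspec = MeanModelSpec(
        effect_model=effect_model,
        time_trend=time_trend,
        link=link,
        theta=tuple(float(t) for t in theta),
        scaling=tuple(float(c) for c in scaling),  # type: ignore[arg-type]
        poly_degree=int(mm.get("poly_degree", 2)),
        n_periods=int(n_periods),
    )
    cspec = CorrelationSpec(
        family=family,
        alpha=tuple(float(a) for a in alpha_triple),  # type: ignore[arg-type]
        decay_inter_period=bool(co.get("decay_inter_period", False)),
    )
    vspec = VarianceSpec(family=v_family, dispersion=float(dispersion))

    contrasts = []
    for idx, raw in enumerate(raw_contrasts):
        contrasts.append(_parse_contrast(raw, idx, mspec, errors))
    if errors:
        raise ConfigError(errors)

    plan = MultiplicityPlan(
        family_alpha=plan_sec.get("family_alpha"),
        power_goal=plan_sec.get("power_goal"),
    )
    # contradictory alpha settings surface early rather than at computation time
    try:
        plan.resolve(contrasts)
    except ValueError as err:
        raise ConfigError([f"plan: {err}"]) from err

    return Bundle(
        layout=layout,
        mean_model=mspec,
        correlation=cspec,
        variance=vspec,
        contrasts=tuple(contrasts),
        plan=plan,
        il_split=float(il_split),
        n_max=int(plan_sec.get("n_max", 1000)),
    )


def _parse_contrast(raw: dict, idx: int, mspec: MeanModelSpec, errors: list[str]) -> ContrastSpec:
    name = raw.get("label", f"contrast_{idx}") if isinstance(raw, dict) else f"contrast_{idx}"
    if not isinstance(raw, dict):
        errors.append(f"contrasts[{idx}]: must be a mapping")
        return ContrastSpec.single(0, mspec.dim)
    _check_keys(f"contrasts[{idx}]", raw, _CONTRAST_KEYS, errors)
    has_effects = "effects" in raw
    has_L = "L" in raw
    if has_effects == has_L:
        errors.append(f"contrasts[{idx}] ({name}): give exactly one of 'effects' or 'L'")
        return ContrastSpec.single(0, mspec.dim)
    if has_effects:
        row = [0.0] * mspec.dim
        base = mspec.treatment_slice.start
        for eff in raw["effects"]:
            if eff not in _EFFECT_NAMES:
                errors.append(
                    f"contrasts[{idx}] ({name}): unknown effect {eff!r} "
                    f"(choose from {_EFFECT_NAMES})"
                )
                return ContrastSpec.single(0, mspec.dim)
            row[base + _EFFECT_NAMES.index(eff)] = 1.0
        L = (tuple(row),)
    else:
        L = tuple(tuple(float(x) for x in r) for r in raw["L"])
        if any(len(r) != mspec.dim for r in L):
            errors.append(f"contrasts[{idx}] ({name}): L rows must have {mspec.dim} entries")
            return ContrastSpec.single(0, mspec.dim)
    ell = tuple(float(x) for x in raw.get("ell", ())) or (0.0,) * len(L)
    alpha = raw.get("alpha")
    try:
        return ContrastSpec(L=L, ell=ell, alpha=alpha, label=name,
                            in_goal=bool(raw.get("in_goal", True)))
    except ValueError as err:
        errors.append(f"contrasts[{idx}] ({name}): {err}")
        return ContrastSpec.single(0, mspec.dim)


def parse_config(path: str | Path) -> Bundle:
    """Parse and validate a YAML config file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        raise ConfigError(["empty configuration file"])
    return parse_mapping(doc)


def serialize(bundle: Bundle) -> str:
    """YAML text that parses back to an equivalent bundle."""
    layout, mspec, cspec = bundle.layout, bundle.mean_model, bundle.correlation
    base = mspec.treatment_slice.start
    contrasts = []
    for c in bundle.contrasts:
        entry: dict[str, Any] = {"label": c.label}
        L = np.asarray(c.L)
        effect_rows = (
            L.shape[0] == 1
            and not L[0, :base].any()
            and set(np.unique(L[0, base:])) <= {0.0, 1.0}
            and np.allclose(c.null_vector(), 0.0)
        )
        if effect_rows:
            entry["effects"] = [
                _EFFECT_NAMES[k] for k in range(3) if L[0, base + k] == 1.0
            ]
        else:
            entry["L"] = [[float(x) for x in row] for row in L]
            entry["ell"] = [float(x) for x in c.null_vector()]
        if c.alpha is not None:
            entry["alpha"] = float(c.alpha)
        if not c.in_goal:
            entry["in_goal"] = False
        contrasts.append(entry)

    doc: dict[str, Any] = {
        "design": {
            "n_periods": layout.n_periods,
            "n_sequences": layout.n_sequences,
            "clusters_per_sequence": list(layout.clusters_per_sequence),
            "cohort_size": list(layout.cohort_size),
            "il_split": bundle.il_split,
            "cohort_type": layout.cohort_type,
        },
        "mean_model": {
            "effect_model": mspec.effect_model,
            "time_trend": mspec.time_trend,
            "link": mspec.link,
            "theta": [float(t) for t in mspec.theta],
            "scaling": [float(c) for c in mspec.scaling],
            "poly_degree": mspec.poly_degree,
        },
        "correlation": {
            "family": cspec.family,
            "within_period": cspec.alpha[0],
            "inter_period": cspec.alpha[1],
            "within_individual": cspec.alpha[2],
            "decay_inter_period": cspec.decay_inter_period,
        },
        "variance": {
            "family": bundle.variance.family,
            "dispersion": bundle.variance.dispersion,
        },
        "contrasts": contrasts,
        "plan": {
            "family_alpha": bundle.plan.family_alpha,
            "power_goal": bundle.plan.power_goal,
            "n_max": bundle.n_max,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_example(name: str = "diabetes_example") -> Bundle:
    """Load a packaged example configuration by name."""
    text = resources.files("mliswd.examples").joinpath(f"{name}.yaml").read_text()
    return parse_mapping(yaml.safe_load(text))
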