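"""YAML configuration for the extraction pipeline.

The config file mirrors the pipeline surface: assist-mask parameters under
``enhance:``, the rule bank (fixed rules and per-category candidate layers)
under ``rules:``, stipple criteria under ``stipple:``, symbol templates under
``symbols:``.  Anything omitted falls back to the shipped defaults, so an
empty file is a valid config.

Example::

    enhance:
      black_intensity_max: 80
      water_blueness_min: 0.9
    rules:
      min_detections: 5
      fixed:
        forest: {layer: greenness/raw, threshold: 0.62, direction: ge}
      candidates:
        heath: [redness/raw, saturation/raw, hue/raw]
    stipple:
      neighbor_radius_m: 25
"""

from __future__ import annotations

import dataclasses

import yaml

from .categories import Category, category_from_name
from .enhance import LayerSpec, MaskParams
from .extract_colour import (
    ExtractionRule,
    PipelineConfig,
    RuleBank,
    default_rule_bank,
    default_templates,
)
from .extract_stipple import StippleParams

__all__ = ["load_config", "load_stipple_params"]


def _dataclass_from_mapping(cls, mapping: dict, defaults):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {f.name: getattr(defaults, f.name) for f in dataclasses.fields(cls)}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _rule_from_mapping(category: Category, mapping: dict) -> ExtractionRule:
    kwargs = dict(mapping)
    layer = LayerSpec.parse(kwargs.pop("layer"))
    return ExtractionRule(category=category, layer=layer, **kwargs)


def _bank_from_mapping(mapping: dict) -> RuleBank:
    base = default_rule_bank()
    fixed = dict(base.fixed)
    for name, rule_map in (mapping.get("fixed") or {}).items():
        cat = category_from_name(name)
        fixed[cat] = _rule_from_mapping(cat, rule_map)
    candidates = dict(base.candidates)
    for name, cand_list in (mapping.get("candidates") or {}).items():
        candidates[category_from_name(name)] = [
            LayerSpec.parse(c) for c in cand_list
        ]
    return RuleBank(
        fixed=fixed,
        candidates=candidates,
        min_detections=mapping.get("min_detections", base.min_detections),
        symbol_radius_m=mapping.get("symbol_radius_m", base.symbol_radius_m),
    )


def load_config(path: str | None = None, seed: int = 0) -> PipelineConfig:
    """Load a pipeline config; ``path=None`` gives the shipped defaults."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    mask_params = _dataclass_from_mapping(
        MaskParams, doc.get("enhance") or {}, MaskParams()
    )
    bank = _bank_from_mapping(doc.get("rules") or {})
    templates = default_templates(
        tau=(doc.get("symbols") or {}).get("tau", 0.8)
    )
    return PipelineConfig(
        bank=bank, templates=templates, mask_params=mask_params,
        seed=doc.get("seed", seed),
    )


def load_stipple_params(path: str | None = None) -> StippleParams:
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    return _dataclass_from_mapping(
        StippleParams, doc.get("stipple") or {}, StippleParams()
    )
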