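"""Bundled executable case studies and their synthetic-data generators.

User models plug in through :func:`register_case`: provide a factory
``variant -> CaseStudyBundle`` (the bundle carries the model's drift/output
functions and its default parameter box) and optionally a seeded data
generator; the case then works everywhere a bundled one does, including the
command line.  Bundled model/box choices can also be referenced from a small
JSON spec file via :func:`load_model_spec`.
"""

import json

from .pk import CaseStudyBundle, PK_VARIANTS, pk_generate, pk_model
from .gln import GLN_VARIANTS, gln_generate, gln_model, gln_phi

REGISTRY = {
    "pk": {"variants": PK_VARIANTS, "model": pk_model, "generate": pk_generate},
    "gln": {"variants": GLN_VARIANTS, "model": gln_model, "generate": gln_generate},
}


def register_case(name, model_factory, generate=None, variants=()):
    """Register a user-supplied case study (plugin hook).

    ``model_factory(variant)`` must return a :class:`CaseStudyBundle`;
    ``generate(seed)`` (optional) must return a ``Dataset`` reproducibly.
    """
    if name in REGISTRY:
        raise ValueError(f"case {name!r} already registered")
    REGISTRY[name] = {"variants": tuple(variants), "model": model_factory,
                      "generate": generate}


def load_model_spec(path):
    """Build a bundle from a JSON spec naming a model id and parameter box.

    Expected keys: ``case``, ``variant``, optional ``box`` (parameter ->
    [lo, hi] log10 pairs overriding the bundle defaults).
    """
    with open(path) as fh:
        spec = json.load(fh)
    unknown = set(spec) - {"case", "variant", "box"}
    if unknown:
        raise ValueError(f"unknown model-spec keys: {sorted(unknown)}")
    case = spec["case"]
    if case not in REGISTRY:
        raise ValueError(f"unknown case {case!r}; have {sorted(REGISTRY)}")
    bundle = REGISTRY[case]["model"](spec["variant"])
    for name, pair in (spec.get("box") or {}).items():
        if name not in bundle.model.param_names:
            raise ValueError(f"box names unknown parameter {name!r}")
        bundle.box[name] = tuple(pair)
    return bundle


__all__ = ["CaseStudyBundle", "PK_VARIANTS", "GLN_VARIANTS", "pk_model",
           "pk_generate", "gln_model", "gln_generate", "gln_phi", "REGISTRY",
           "register_case", "load_model_spec"]
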