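"""Built-in parameter presets.

These are *synthetic illustrative fixtures*, not measured parameter sets: the
values are chosen to be physiologically plausible for the named host/process
combination (yields and maintenance in the range tabulated for glucose-grown
cultures, lab-scale reactor volumes and pump limits) so that examples, tests
and smoke runs work end to end. Users with estimated parameters for a real
strain should supply their own config file; :func:`fedbatch.config.load_config`
accepts the same schema.
"""

from __future__ import annotations

from .config import RunConfig, config_from_dict

__all__ = ["builtin_presets", "get_preset", "preset_names"]

# E. coli-like host on glucose: growth stage with mostly growth-coupled
# production, growth-arrested stage (e.g. microaerobic shift) with a higher
# non-growth-associated rate.
_ECOLI_SYNTHETIC = {
    "process": {
        "v0": 2.0,      # L at feed start
        "x0": 20.0,     # g biomass (10 g/L)
        "p0": 0.0,      # g product
        "s_f": 500.0,   # g/L glucose in the feed
        "v_max": 5.0,   # L final volume
        "f_min": 0.0,   # L/h
        "f_max": 0.5,   # L/h pump limit
    },
    "stage1": {
        "y_xs": 0.50,   # g/g, aerobic glucose growth
        "y_ps": 0.45,   # g/g
        "m_s": 0.04,    # g/g/h
        "alpha": 0.10,  # g/g growth-associated production
        "beta": 0.02,   # g/g/h
        "mu_max": 0.60, # 1/h
    },
    "stage2": {
        "y_xs": 0.50,   # unused while mu = 0; kept for completeness
        "y_ps": 0.50,
        "m_s": 0.02,
        "alpha": 0.0,
        "beta": 0.15,   # g/g/h growth-decoupled production
    },
    "grid": {
        "strategy": "constant",
        "param_min": 0.01,  # L/h
        "param_max": 0.08,
        "n_param": 50,
        "frac_min": 0.05,
        "frac_max": 1.0,
        "n_frac": 50,
    },
    "options": {"objective": "rate"},
}

# S. cerevisiae-like host: aerobic growth stage with little product, ethanol
# formation under nitrogen starvation in the growth-arrested stage.
_YEAST_SYNTHETIC = {
    "process": {
        "v0": 1.0,
        "x0": 5.0,      # g biomass (5 g/L)
        "p0": 0.0,
        "s_f": 400.0,   # g/L glucose
        "v_max": 3.0,
        "f_min": 0.0,
        "f_max": 0.3,
    },
    "stage1": {
        "y_xs": 0.45,
        "y_ps": 0.10,
        "m_s": 0.02,
        "alpha": 0.05,
        "beta": 0.0,
        "mu_max": 0.40,
    },
    "stage2": {
        "y_xs": 0.45,
        "y_ps": 0.45,   # g ethanol / g glucose under starvation
        "m_s": 0.01,
        "alpha": 0.0,
        "beta": 0.25,   # g/g/h
    },
    "grid": {
        "strategy": "exponential",
        "param_min": 0.05,  # 1/h
        "param_max": 0.35,
        "n_param": 50,
        "frac_min": 0.05,
        "frac_max": 1.0,
        "n_frac": 50,
    },
    "options": {"objective": "rate"},
}

_PRESETS = {
    "ecoli-synthetic": _ECOLI_SYNTHETIC,
    "yeast-synthetic": _YEAST_SYNTHETIC,
}


def preset_names() -> list:
    """Names of the bundled presets."""
    return sorted(_PRESETS)


def builtin_presets() -> dict:
    """All bundled presets as fully validated :class:`RunConfig` objects."""
    return {name: config_from_dict(data) for name, data in _PRESETS.items()}


def get_preset(name: str) -> RunConfig:
    """Look up one preset by name; unknown names list the available ones."""
    try:
        data = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return config_from_dict(data)
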