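"""YAML configuration for webs, competition structure, rates and protocol.

A configuration file has up to five sections::

    web:          file: web.tsv   |  n_basal/n_consumers/links/seed
    competition:  structure: hierarchical|weakened|intransitive, w,
                  target_RI, seed, rank_order
    rates:        c_range, spacing, seed, e_basal, c_consumer, e_consumer,
                  mu, phi, U
    protocol:    t_burnin, t_avg, threshold, rtol, atol, fcl_convention
    sweep:       U_max, U_step, mode, method, cross_validate, seed

All rate defaults are prefilled (e_basal 0.2, c_consumer 0.625,
e_consumer 0.05, mu = phi = 0.05, colonization range [0.45, 0.8] evenly
spaced). Unknown keys raise a :class:`ConfigError` naming the offending
key.
"""

from __future__ import annotations

import yaml

from .competition import hierarchical_H, intransitive_H, weakened_H
from .sweep import default_U_grid
from .webgen import FoodWeb, assign_cc_tradeoff, generate_web, read_web_tsv

__all__ = ["ConfigError", "load_config", "build_model", "sweep_options"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_ALLOWED = {
    "web": {"file", "n_basal", "n_consumers", "links", "seed", "n_layers"},
    "competition": {"structure", "w", "target_RI", "seed", "rank_order"},
    "rates": {"c_range", "spacing", "seed", "e_basal", "c_consumer",
              "e_consumer", "mu", "phi", "U"},
    "protocol": {"t_burnin", "t_avg", "threshold", "rtol", "atol",
                 "fcl_convention"},
    "sweep": {"U_max", "U_step", "mode", "method", "cross_validate", "seed"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for section, content in cfg.items():
        if section not in _ALLOWED:
            raise ConfigError(f"unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in content:
            if key not in _ALLOWED[section]:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r}"
                )
    return cfg


def _build_web(cfg: dict) -> FoodWeb:
    sec = cfg.get("web") or {}
    if "file" in sec:
        return read_web_tsv(sec["file"])
    try:
        return generate_web(
            n_P=int(sec["n_basal"]),
            n_A=int(sec["n_consumers"]),
            L=int(sec["links"]),
            seed=int(sec.get("seed", 0)),
            n_layers=sec.get("n_layers"),
        )
    except KeyError as err:
        raise ConfigError(
            f"web section needs either 'file' or n_basal/n_consumers/links; "
            f"missing {err.args[0]!r}"
        ) from None


def _build_competition(cfg: dict, n_P: int):
    sec = cfg.get("competition") or {}
    structure = sec.get("structure", "hierarchical")
    if structure == "hierarchical":
        return hierarchical_H(n_P, rank_order=sec.get("rank_order"))
    if structure == "weakened":
        return weakened_H(n_P, float(sec.get("w", 1.0)))
    if structure == "intransitive":
        return intransitive_H(n_P, float(sec.get("target_RI", 1.0)),
                              seed=sec.get("seed"))
    raise ConfigError(f"unknown competition structure {structure!r}")


def _build_params(cfg: dict, web: FoodWeb):
    sec = dict(cfg.get("rates") or {})
    c_range = tuple(sec.pop("c_range", (0.45, 0.8)))
    return assign_cc_tradeoff(
        web,
        c_range=c_range,
        spacing=sec.pop("spacing", "even"),
        seed=sec.pop("seed", None),
        U=float(sec.pop("U", 0.0)),
        e_basal=float(sec.pop("e_basal", 0.2)),
        c_consumer=float(sec.pop("c_consumer", 0.625)),
        e_consumer=float(sec.pop("e_consumer", 0.05)),
        mu=float(sec.pop("mu", 0.05)),
        phi=float(sec.pop("phi", 0.05)),
    )


def build_model(path_or_cfg):
    """Construct a :class:`~webpatch.model.PatchOccupancyModel` from a config."""
    from .model import PatchOccupancyModel

    cfg = (path_or_cfg if isinstance(path_or_cfg, dict)
           else load_config(path_or_cfg))
    web = _build_web(cfg)
    comp = _build_competition(cfg, web.n_basal)
    params = _build_params(cfg, web)
    prot = cfg.get("protocol") or {}
    return PatchOccupancyModel(
        web,
        competition=comp,
        params=params,
        threshold=float(prot.get("threshold", 1e-6)),
        fcl_convention=prot.get("fcl_convention", "links"),
    )


def protocol_options(cfg: dict) -> dict:
    """ODE-protocol keyword arguments from the protocol section."""
    prot = cfg.get("protocol") or {}
    out = {}
    for key in ("t_burnin", "t_avg", "rtol", "atol"):
        if key in prot:
            out[key] = float(prot[key])
    return out


def sweep_options(cfg: dict) -> dict:
    """Keyword arguments for ``PatchOccupancyModel.sweep`` from a config."""
    sec = cfg.get("sweep") or {}
    out = {
        "mode": sec.get("mode", "full"),
        "method": sec.get("method", "auto"),
        "cross_validate": int(sec.get("cross_validate", 0)),
        "seed": sec.get("seed"),
    }
    if "U_max" in sec or "U_step" in sec:
        out["U_grid"] = default_U_grid(
            stop=float(sec.get("U_max", 0.95)),
            step=float(sec.get("U_step", 0.005)),
        )
    return out
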