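"""Run configuration: YAML schema, validation, seed management.

A run configuration bundles the network, stimulus, optional clamp, backend,
duration and master seed.  Every field has a default drawn from the standard
decision-network parameter table, so an empty config describes the
full-size fully connected network.  Validation is strict: unknown keys and
grid-misaligned times are collected and reported together.

Units by key suffix/name: times in ms, rates in spikes/s, conductances nS,
capacitance pF, potentials mV, magnesium mM.
"""

from __future__ import annotations

import dataclasses
import io
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .network import NetworkSpec, decision_network_spec, sparse_epsilons
from .stimulus import ClampSpec, StimulusSpec

__all__ = ["RunConfig", "load_and_validate", "dump_config", "derive_seeds"]

_NETWORK_KEYS = {
    "scale", "f", "w_plus", "w_minus", "w_minus_form", "delay", "dt",
    "N_E", "N_I", "eps_base", "eps_selective", "eps_inhibitory", "sparse",
}
_STIM_KEYS = {
    "nu_ext", "mu0", "rho_A", "rho_B", "coherence", "resample_interval",
    "rate_sd", "window",
}
_CLAMP_KEYS = {"sources", "window", "include_conductance"}
_TOP_KEYS = {"network", "stimulus", "clamp", "backend", "T", "master_seed",
             "record_spikes", "output_dir"}


@dataclass
class RunConfig:
    network: NetworkSpec
    stimulus: StimulusSpec
    clamp: ClampSpec | None
    backend: str
    T: float
    master_seed: int
    record_spikes: bool = True
    output_dir: str = "."
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def dt(self) -> float:
        return self.network.dt


class ConfigError(ValueError):
    """Raised with the full list of violations found in a config."""


def _is_multiple(x, dt):
    return abs(round(x / dt) - x / dt) <= 1e-9


def load_and_validate(source) -> RunConfig:
    """Build a RunConfig from a YAML file path, stream, or mapping.

    Omitted fields take the standard table defaults; all violations are
    reported at once.
    """
    if isinstance(source, dict):
        data = dict(source)
    elif hasattr(source, "read"):
        data = yaml.safe_load(source) or {}
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    errors = []
    for k in set(data) - _TOP_KEYS:
        errors.append(f"unknown top-level key: {k!r}")

    net = dict(data.get("network") or {})
    for k in set(net) - _NETWORK_KEYS:
        errors.append(f"unknown network key: {k!r}")
    stim = dict(data.get("stimulus") or {})
    for k in set(stim) - _STIM_KEYS:
        errors.append(f"unknown stimulus key: {k!r}")
    clamp_d = data.get("clamp")
    if clamp_d is not None:
        for k in set(clamp_d) - _CLAMP_KEYS:
            errors.append(f"unknown clamp key: {k!r}")

    backend = data.get("backend", "approximate")
    if backend not in ("approximate", "exact", "exact_per_synapse"):
        errors.append(f"unknown backend: {backend!r}")
    T = float(data.get("T", 4000.0))
    master_seed = int(data.get("master_seed", 0))

    dt = float(net.pop("dt", 0.1))
    delay = float(net.pop("delay", 0.5))
    sparse = bool(net.pop("sparse", False))
    eps_base = float(net.pop("eps_base", 0.2))
    eps_sel = float(net.pop("eps_selective", eps_base))
    eps_inh = float(net.pop("eps_inhibitory", eps_base))
    epsilons = sparse_epsilons(eps_base, eps_sel, eps_inh) if sparse else None

    spec = None
    if not errors:
        try:
            spec = decision_network_spec(dt=dt, delay=delay, epsilons=epsilons, **net)
        except (TypeError, ValueError) as e:
            errors.append(str(e))

    window = tuple(stim.pop("window", (1000.0, 3000.0)))
    stimulus = None
    try:
        stimulus = StimulusSpec(window=window, **stim)
    except (TypeError, ValueError) as e:
        errors.append(str(e))

    clamp = None
    if clamp_d is not None:
        try:
            kw = dict(clamp_d)
            if "window" in kw:
                kw["window"] = tuple(kw["window"])
            clamp = ClampSpec(**kw)
        except (TypeError, ValueError) as e:
            errors.append(str(e))

    # grid alignment
    if not _is_multiple(T, dt):
        errors.append(f"T={T} is not a multiple of dt={dt}")
    if not _is_multiple(delay, dt) or delay < dt - 1e-12:
        errors.append(f"delay={delay} is not a multiple of dt={dt} (or < dt)")
    if stimulus is not None:
        for w in stimulus.window:
            if not _is_multiple(w, dt):
                errors.append(f"stimulus window edge {w} not a multiple of dt={dt}")
    if clamp is not None and not _is_multiple(clamp.window[1], dt):
        errors.append(f"clamp release {clamp.window[1]} not a multiple of dt={dt}")

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        network=spec, stimulus=stimulus, clamp=clamp, backend=backend, T=T,
        master_seed=master_seed,
        record_spikes=bool(data.get("record_spikes", True)),
        output_dir=str(data.get("output_dir", ".")),
        raw=data,
    )


def dump_config(cfg: RunConfig, stream=None) -> str | None:
    """Serialize the resolved configuration (round-trips via load_and_validate)."""
    data = {
        "backend": cfg.backend,
        "T": cfg.T,
        "master_seed": cfg.master_seed,
        "record_spikes": cfg.record_spikes,
        "output_dir": cfg.output_dir,
        "network": dict(cfg.raw.get("network") or {}),
        "stimulus": {
            **{f.name: getattr(cfg.stimulus, f.name)
               for f in dataclasses.fields(StimulusSpec) if f.name != "window"},
            "window": list(cfg.stimulus.window),
        },
    }
    if cfg.clamp is not None:
        data["clamp"] = {
            "sources": dict(cfg.clamp.sources),
            "window": list(cfg.clamp.window),
            "include_conductance": cfg.clamp.include_conductance,
        }
    if stream is None:
        buf = io.StringIO()
        yaml.safe_dump(data, buf, sort_keys=True)
        return buf.getvalue()
    yaml.safe_dump(data, stream, sort_keys=True)
    return None


def derive_seeds(master_seed: int, labels) -> dict:
    """Deterministic, collision-resistant per-stream seeds below 2**31.

    Independent named streams (connectivity, background, stimulus, bootstrap,
    ...) are derived by mixing the master seed with a label hash.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate stream labels")
    out = {}
    for lab in labels:
        h = zlib.crc32(str(lab).encode())
        ss = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, h])
        out[lab] = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    return out
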