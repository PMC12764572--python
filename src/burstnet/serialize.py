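"""Plain-text serialization: sparse weight triplets and config files."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["save_weight_triplets", "load_weight_triplets",
           "config_to_text", "config_from_text"]


def save_weight_triplets(path, W: np.ndarray, delays=None,
                         distances=None) -> None:
    """Write nonzero weights as ``pre post J delay distance`` rows."""
    pre, post = np.nonzero(W)
    with open(path, "w") as fh:
        fh.write("# pre post J delay distance\n")
        for i, j in zip(pre, post):
            d = 0.0 if delays is None else float(delays[i, j])
            r = 0.0 if distances is None else float(distances[i, j])
            fh.write(f"{i} {j} {float(W[i, j])!r} {d!r} {r!r}\n")


def load_weight_triplets(path, shape) -> np.ndarray:
    W = np.zeros(shape)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            W[int(toks[0]), int(toks[1])] = float(toks[2])
    return W


def config_to_text(cfg, path) -> None:
    """Dump a config dataclass as ``key = value`` lines."""
    with open(path, "w") as fh:
        fh.write(f"# {type(cfg).__name__}\n")
        for f in dataclasses.fields(cfg):
            fh.write(f"{f.name} = {getattr(cfg, f.name)!r}\n")


def config_from_text(cls, path):
    """Rebuild a config dataclass from ``key = value`` lines."""
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key in names:
                kwargs[key] = eval(val, {"__builtins__": {}}, {})
    return cls(**kwargs)
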