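"""CSV I/O for channel-by-frame grids.

Rows are channels, columns frames; metadata travels as ``# key: value``
comment lines before the data.  The same dialect is used for
cochleagrams, reduced stimuli and latent trajectories.
"""

from __future__ import annotations

import numpy as np

__all__ = ["save_grid", "load_grid"]


def save_grid(path, values: np.ndarray, meta: dict | None = None) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        for row in values:
            fh.write(",".join(f"{x:.8g}" for x in row) + "\n")


def load_grid(path):
    """Return (values, meta); numeric metadata values are parsed as float."""
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    v = v.strip()
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        meta[k.strip()] = v
                continue
            rows.append([float(x) for x in line.split(",")])
    return np.asarray(rows), meta
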