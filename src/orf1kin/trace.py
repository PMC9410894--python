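"""The Trace container: a time/extension/force record with metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """A single-molecule record sampled at a fixed rate.

    Attributes
    ----------
    time : ndarray
        Sample times (s), strictly ascending.
    extension : ndarray
        End-to-end extension (nm), >= 0.
    force : ndarray
        Tension (pN).
    metadata : dict
        Provenance: substrate length (``substrate_nt``), preset name,
        seed, protocol name, segment boundaries, noise parameters.
    channels : dict
        Optional derived channels (e.g. ``ext_nm_per_nt``,
        ``ext_relative``) added by normalization.
    """

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.extension.size != n or self.force.size != n:
            raise ValueError("time, extension and force must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly ascending")

    def __len__(self) -> int:
        return self.time.size

    def copy(self) -> "Trace":
        return Trace(self.time.copy(), self.extension.copy(), self.force.copy(),
                     dict(self.metadata),
                     {k: v.copy() for k, v in self.channels.items()})

    def segment_bounds(self, label: str) -> tuple[float, float]:
        """[t_start, t_end) of a named protocol segment from metadata."""
        segs = self.metadata.get("segments")
        if not segs:
            raise KeyError("trace metadata carries no segment boundaries")
        for i, (name, t0) in enumerate(segs):
            if name == label:
                t1 = segs[i + 1][1] if i + 1 < len(segs) else np.inf
                return float(t0), float(t1)
        raise KeyError(f"no segment labelled {label!r}; "
                       f"have {[s[0] for s in segs]}")

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t in [t0, t1), metadata shared."""
        m = (self.time >= t0) & (self.time < t1)
        return Trace(self.time[m], self.extension[m], self.force[m],
                     dict(self.metadata),
                     {k: v[m] for k, v in self.channels.items()})

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time, "extension_nm": self.extension,
                "force_pN": self.force}
        data.update(self.channels)
        return pd.DataFrame(data)
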