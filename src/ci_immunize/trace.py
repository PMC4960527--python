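"""Attack traces: per-removal records of q, giant component, and the monitor.

Component sizes are expensive (O(N) each), so they are measured on a thinned
grid of steps; unmeasured entries are NaN.  The giant component is stored as
a fraction of the initial N, the second-largest cluster as a node count (it
is sub-extensive and would vanish as a fraction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttackTrace"]

_COLUMNS = ("step", "node_removed", "q", "giant", "second", "lambda")


@dataclass
class AttackTrace:
    """Ordered removals with the q, G(q), second-cluster and monitor traces."""

    n0: int
    removal_order: np.ndarray        # node removed at each step
    q: np.ndarray                    # removed fraction after each step
    giant: np.ndarray                # G(q) as a fraction of n0; NaN off-grid
    second: np.ndarray               # second-largest cluster (node count); NaN off-grid
    lam: np.ndarray                  # eigenvalue monitor; NaN where not applicable
    qc_estimate: float
    stop_reason: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return int(self.removal_order.size)

    def measured(self) -> np.ndarray:
        """Indices of steps where components were actually computed."""
        return np.flatnonzero(~np.isnan(self.giant))

    def second_peak_q(self) -> float:
        """q at the measured peak of the second-largest cluster."""
        idx = np.flatnonzero(~np.isnan(self.second))
        if idx.size == 0:
            return math.nan
        return float(self.q[idx[np.argmax(self.second[idx])]])

    def first_q_giant_below(self, frac: float) -> float:
        """First measured q where G(q) drops below ``frac``."""
        idx = self.measured()
        below = idx[self.giant[idx] <= frac]
        return float(self.q[below[0]]) if below.size else math.nan

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n0 {self.n0}\n")
            fh.write(f"# qc_estimate {self.qc_estimate!r}\n")
            fh.write(f"# stop_reason {self.stop_reason}\n")
            fh.write(f"# meta {json.dumps(self.meta, default=str)}\n")
            fh.write("\t".join(_COLUMNS) + "\n")
            for t in range(self.n_removed):
                fh.write(
                    f"{t}\t{int(self.removal_order[t])}\t{self.q[t]:.8g}\t"
                    f"{self.giant[t]:.8g}\t{self.second[t]:.8g}\t{self.lam[t]:.8g}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "AttackTrace":
        header: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, val = line[2:].partition(" ")
                    header[key] = val
                elif line and not line.startswith("step\t"):
                    rows.append(line.split("\t"))
        arr = np.asarray(rows, dtype=np.float64) if rows else np.zeros((0, 6))
        return cls(
            n0=int(header.get("n0", 0)),
            removal_order=arr[:, 1].astype(np.int64),
            q=arr[:, 2],
            giant=arr[:, 3],
            second=arr[:, 4],
            lam=arr[:, 5],
            qc_estimate=float(header.get("qc_estimate", "nan")),
            stop_reason=header.get("stop_reason", ""),
            meta=json.loads(header.get("meta", "{}")),
        )

    def summary(self) -> dict:
        """JSON-ready summary; every number is recomputable from the trace."""
        idx = self.measured()
        return {
            "schema_version": 1,
            "n0": self.n0,
            "n_removed": self.n_removed,
            "qc_estimate": self.qc_estimate,
            "stop_reason": self.stop_reason,
            "final_q": float(self.q[-1]) if self.n_removed else 0.0,
            "final_giant": float(self.giant[idx[-1]]) if idx.size else math.nan,
            "second_peak_q": self.second_peak_q(),
            **{k: v for k, v in self.meta.items()},
        }

    def plot(self, ax=None):  # pragma: no cover - convenience helper
        """Simple curve dump: G(q), second cluster (scaled) and the monitor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = self.measured()
        ax.plot(self.q[idx], self.giant[idx], "r.", label="G(q)")
        sec = self.second[idx]
        if np.nanmax(sec) > 0:
            ax.plot(self.q[idx], sec / np.nanmax(sec) * np.nanmax(self.giant[idx]),
                    "b^", ms=3, label="second (scaled)")
        if not np.all(np.isnan(self.lam)):
            ax.plot(self.q, self.lam / np.nanmax(self.lam), "k+", ms=2,
                    label="monitor (scaled)")
        ax.set_xlabel("q")
        ax.legend()
        return ax
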