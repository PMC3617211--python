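"""Phase diagrams over the (r2 x r1) control-parameter plane.

Each grid cell inverts the control-parameter map back to a rate set
(``k1 = r1 * k_m1``, ``k2 = r2 * k_m2`` with the backward rates and ``k3``
fixed as anchors), computes the limiting distribution from fully damaged
DNA and colors the cell: RED when repaired with probability > 1/2, GREEN
when the unrepaired mass is dominated by the trapped intermediate, BLUE
when the substrate dominates.

Two degenerate slices are supported.  With the first forward step removed
(``k1 = 0``) the ratio r1 loses meaning; the first axis instead sweeps the
compensatory-to-backward ratio ``k3 / k_m1`` (a reconstruction, flagged in
the export metadata).  With the first backward step removed (``k_m1 = 0``)
only r2 is swept, at a fixed anchor ``k1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classification import PhaseColor, phase_color
from .errors import GridError
from .kinetics import FULLY_DAMAGED, PathwayDistribution, RateSet, limiting_distribution

__all__ = [
    "SliceMode",
    "GridSpec",
    "PhaseDiagram",
    "default_grid",
    "rates_from_grid_point",
    "compute_phase_diagram",
    "export_phase_diagram",
    "load_phase_diagram_colors",
]


class SliceMode(enum.Enum):
    FULL = "FULL"
    K1_ZERO = "K1_ZERO"  # F1 knocked out; axis 1 sweeps k3/k_m1
    KM1_ZERO = "KM1_ZERO"  # R1 knocked out; only r2 is swept


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced grid over the control plane plus the anchor rates.

    ``r1_values`` carries the first axis: r1 = k1/k_m1 in FULL mode, the
    replacement ratio k3/k_m1 in K1_ZERO mode, and must be None (single
    row) in KM1_ZERO mode, where ``k1_anchor`` supplies the fixed k1.
    """

    r1_values: Optional[tuple[float, ...]]
    r2_values: tuple[float, ...]
    k_m1: float
    k_m2: float
    k3: float
    mode: SliceMode = SliceMode.FULL
    k1_anchor: float = 1.0

    def __post_init__(self) -> None:
        r2 = tuple(float(v) for v in self.r2_values)
        if len(r2) == 0:
            raise GridError("r2 grid is empty")
        if any(v <= 0 for v in r2):
            raise GridError("grid values must be positive")
        object.__setattr__(self, "r2_values", r2)
        if self.mode is SliceMode.KM1_ZERO:
            if self.r1_values is not None:
                raise GridError("KM1_ZERO sweeps only r2; r1_values must be None")
            if self.k1_anchor <= 0:
                raise GridError("KM1_ZERO needs a positive k1 anchor")
        else:
            if self.r1_values is None or len(self.r1_values) == 0:
                raise GridError("r1 grid is empty")
            r1 = tuple(float(v) for v in self.r1_values)
            if any(v <= 0 for v in r1):
                raise GridError("grid values must be positive")
            object.__setattr__(self, "r1_values", r1)
        for name in ("k_m1", "k_m2", "k3"):
            if getattr(self, name) < 0:
                raise GridError(f"anchor {name} must be nonnegative")
        if self.mode is SliceMode.FULL and self.k_m1 <= 0:
            raise GridError("FULL mode needs k_m1 > 0 (r1 would be undefined)")
        if self.mode is SliceMode.K1_ZERO and self.k_m1 <= 0:
            raise GridError("K1_ZERO mode sweeps k3/k_m1 and needs k_m1 > 0")
        if self.k_m2 <= 0:
            raise GridError("anchors need k_m2 > 0 (r2 would be undefined)")

    @property
    def axis1(self) -> tuple[float, ...]:
        return (1.0,) if self.mode is SliceMode.KM1_ZERO else self.r1_values

    @property
    def axis1_name(self) -> str:
        return {"FULL": "r1", "K1_ZERO": "k3_over_k_m1", "KM1_ZERO": "fixed"}[self.mode.value]


def default_grid(
    rb: float = 1.0,
    k_m1: float = 0.1,
    k3: float = 0.1,
    n_points: int = 41,
    lo: float = 1e-2,
    hi: float = 1e2,
    mode: SliceMode = SliceMode.FULL,
) -> GridSpec:
    """Default regime grids: log-spaced axes over [1e-2, 1e2] with the
    backward-rate ratio rb = k_m1/k_m2 selecting the regime (0.1 small,
    1 intermediate, 100 large)."""
    if rb <= 0:
        raise GridError("rb must be positive")
    values = tuple(np.geomspace(lo, hi, n_points))
    return GridSpec(
        r1_values=None if mode is SliceMode.KM1_ZERO else values,
        r2_values=values,
        k_m1=k_m1,
        k_m2=k_m1 / rb,
        k3=k3,
        mode=mode,
    )


def rates_from_grid_point(spec: GridSpec, r1: float, r2: float) -> RateSet:
    """Invert the control-parameter map at one grid point."""
    k2 = r2 * spec.k_m2
    if spec.mode is SliceMode.FULL:
        return RateSet(k1=r1 * spec.k_m1, k_m1=spec.k_m1, k2=k2, k_m2=spec.k_m2, k3=spec.k3)
    if spec.mode is SliceMode.K1_ZERO:
        # r1 is reinterpreted as k3/k_m1; the k3 anchor is overridden.
        return RateSet(k1=0.0, k_m1=spec.k_m1, k2=k2, k_m2=spec.k_m2, k3=r1 * spec.k_m1)
    return RateSet(k1=spec.k1_anchor, k_m1=0.0, k2=k2, k_m2=spec.k_m2, k3=spec.k3)


@dataclass(frozen=True)
class PhaseDiagram:
    spec: GridSpec
    colors: np.ndarray  # (len(axis1), len(r2)) of PhaseColor
    distributions: np.ndarray  # same shape, of PathwayDistribution

    def __post_init__(self) -> None:
        shape = (len(self.spec.axis1), len(self.spec.r2_values))
        if self.colors.shape != shape or self.distributions.shape != shape:
            raise GridError(f"matrix shape {self.colors.shape} does not match grid {shape}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a1 in enumerate(self.spec.axis1):
            for j, r2 in enumerate(self.spec.r2_values):
                d = self.distributions[i, j]
                rows.append(
                    {
                        "r1": a1,
                        "r2": r2,
                        "S": d.s,
                        "I": d.i,
                        "P": d.p,
                        "color": self.colors[i, j].value,
                    }
                )
        return pd.DataFrame(rows, columns=["r1", "r2", "S", "I", "P", "color"])


def compute_phase_diagram(
    spec: GridSpec, initial: PathwayDistribution = FULLY_DAMAGED
) -> PhaseDiagram:
    """Classify every grid cell (deterministic; exact limiting distributions)."""
    n1, n2 = len(spec.axis1), len(spec.r2_values)
    colors = np.empty((n1, n2), dtype=object)
    dists = np.empty((n1, n2), dtype=object)
    for i, a1 in enumerate(spec.axis1):
        for j, r2 in enumerate(spec.r2_values):
            rates = rates_from_grid_point(spec, a1, r2)
            d = limiting_distribution(rates, initial)
            dists[i, j] = d
            colors[i, j] = phase_color(d)
    return PhaseDiagram(spec=spec, colors=colors, distributions=dists)


def export_phase_diagram(diagram: PhaseDiagram, path, image_path=None) -> None:
    """Write the long-format TSV (r1, r2, S, I, P, color); optionally a raster.

    A comment header records the slice mode and anchors, including that the
    K1_ZERO first axis is the reconstructed ratio k3/k_m1.
    """
    frame = diagram.to_frame()
    spec = diagram.spec
    header = (
        f"# slice={spec.mode.value} axis1={spec.axis1_name} "
        f"k_m1={spec.k_m1} k_m2={spec.k_m2} k3={spec.k3}\n"
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)
    if image_path is not None:
        _save_raster(diagram, image_path)


_COLOR_RGB = {
    PhaseColor.RED: (0.85, 0.15, 0.15),
    PhaseColor.GREEN: (0.15, 0.65, 0.2),
    PhaseColor.BLUE: (0.2, 0.3, 0.85),
}


def _save_raster(diagram: PhaseDiagram, image_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = np.array(
        [[_COLOR_RGB[c] for c in row] for row in diagram.colors]
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.transpose(rgb, (1, 0, 2)), origin="lower", aspect="auto")
    ax.set_xlabel(diagram.spec.axis1_name)
    ax.set_ylabel("r2")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


def load_phase_diagram_colors(path) -> pd.DataFrame:
    """Re-read an exported TSV; returns the long table with colors.

    Round-trips reproduce the color matrix exactly (colors are categorical
    strings, untouched by float formatting)."""
    return pd.read_csv(path, sep="\t", comment="#")
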