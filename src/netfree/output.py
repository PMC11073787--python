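"""Count-series (gdat) and visualization output.

gdat is the BioNetGen convention: a ``#`` header naming the columns
(``time`` first), then whitespace-delimited scientific-notation rows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CountSeries", "write_gdat", "read_gdat", "format_gdat",
           "write_viz_frame", "format_viz_frame"]

_FMT = "%.15e"


@dataclass
class CountSeries:
    """One observable's time series (times strictly increasing, aligned to
    iteration boundaries)."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def format_gdat(series: Sequence[CountSeries]) -> str:
    names = [s.name for s in series]
    header = "#" + " ".join(f"{n:>22s}" for n in ["time"] + names)
    lines = [header]
    if series:
        n_rows = len(series[0].times)
        for s in series:
            if len(s.times) != n_rows:
                raise ValueError("all series must share the time grid")
        for i in range(n_rows):
            row = [series[0].times[i]] + [s.values[i] for s in series]
            lines.append(" " + " ".join(_FMT % v for v in row))
    return "\n".join(lines) + "\n"


def write_gdat(series: Sequence[CountSeries], path) -> None:
    with open(path, "w") as fh:
        fh.write(format_gdat(series))


def read_gdat(path) -> pd.DataFrame:
    """Read a gdat table into a DataFrame indexed by time."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing gdat header")
        names = header[1:].split()
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return pd.DataFrame(columns=names[1:]).rename_axis("time")
    df = pd.DataFrame(data, columns=names)
    return df.set_index("time")


def world_series(world) -> list[CountSeries]:
    """Extract the accumulated observable counts of a world."""
    times = np.asarray(world.count_times)
    rows = np.asarray(world.count_rows, dtype=float)
    out = []
    for col, name in enumerate(world.observable_names()):
        out.append(CountSeries(name, times, rows[:, col]))
    return out


def format_viz_frame(world) -> str:
    """ASCII frame: species key, id, x y z (μm); surface molecules add
    their triangle normal."""
    lines = []
    for mid in sorted(world.volume_molecules):
        mol = world.volume_molecules[mid]
        x, y, z = mol.pos
        lines.append(f"{mol.species_key} {mid} "
                     f"{x:.9e} {y:.9e} {z:.9e}")
    for mid in sorted(world.surface_molecules):
        mol = world.surface_molecules[mid]
        obj = world.objects[mol.object_name]
        n = obj.mesh.normals()[mol.triangle]
        x, y, z = mol.pos
        lines.append(f"{mol.species_key} {mid} "
                     f"{x:.9e} {y:.9e} {z:.9e} "
                     f"{n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_viz_frame(world, iteration: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_viz_frame(world))
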