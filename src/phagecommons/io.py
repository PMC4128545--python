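"""Tabular I/O with provenance headers.

Every artifact is a tab-separated table preceded by ``#`` comment lines that
echo the package version and the fully resolved configuration that produced
it, so any output can be re-run exactly.  Numeric columns are written in
full-precision scientific notation (densities span ~10 orders of magnitude)
and round-trip bit-exactly.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .model import ModelParameters, StateVector
from .simulate import SimulationSpec, Trajectory

__all__ = [
    "write_table",
    "read_table",
    "read_header",
    "write_trajectory",
    "read_trajectory",
]

_FLOAT_FORMAT = "%.17g"  # shortest round-trip representation is wider than needed


def _header_lines(
    comments: Optional[dict[str, object]], timestamp: bool
) -> list[str]:
    lines = [f"# phagecommons {__version__}"]
    if timestamp:
        lines.append(f"# written {datetime.datetime.now().isoformat()}")
    for key, value in (comments or {}).items():
        lines.append(f"# {key} = {value!r}")
    return lines


def write_table(
    frame: pd.DataFrame,
    path: Union[str, Path],
    comments: Optional[dict[str, object]] = None,
    timestamp: bool = False,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with a commented provenance header.

    ``comments`` is echoed one ``# key = value`` line per entry; the
    timestamp line is off by default so identical configurations produce
    byte-identical files.
    """
    path = Path(path)
    body = frame.to_csv(sep="\t", index=index, float_format=_FLOAT_FORMAT)
    path.write_text("\n".join(_header_lines(comments, timestamp)) + "\n" + body)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def read_header(path: Union[str, Path]) -> dict[str, str]:
    """Parse the ``# key = value`` comment header of a written table."""
    result: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.startswith("#"):
            break
        line = raw[1:].strip()
        if "=" in line:
            key, _, value = line.partition("=")
            result[key.strip()] = value.strip()
    return result


# ---------------------------------------------------------------------------
# Trajectory round-trip
# ---------------------------------------------------------------------------

_STATE_FIELDS = ("B", "R", "P_G", "P_W", "I_G", "I_W", "E")


def write_trajectory(
    traj: Trajectory,
    path: Union[str, Path],
    extra: Optional[dict[str, object]] = None,
    timestamp: bool = False,
) -> None:
    """Write a trajectory with enough header metadata to re-run it exactly."""
    comments: dict[str, object] = {}
    for name, value in traj.params.to_dict().items():
        comments[f"param.{name}"] = value
    for name, value in traj.spec.initial_state.items():
        comments[f"initial.{name}"] = value
    comments["spec.t_end"] = traj.spec.t_end
    comments["spec.dt"] = traj.spec.dt
    comments["spec.history_mode"] = traj.spec.history_mode
    comments["spec.output_thin"] = traj.spec.resolved_thin
    comments["clamp_events"] = traj.clamp_events
    comments.update(extra or {})
    write_table(traj.frame, path, comments=comments, timestamp=timestamp)


def _unquote(value: str) -> str:
    if len(value) >= 2 and value[0] == value[-1] and value[0] in "'\"":
        return value[1:-1]
    return value


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Reconstruct a Trajectory (frame, spec and clamp count) from its TSV."""
    header = read_header(path)
    params = ModelParameters.from_dict(
        {
            key.removeprefix("param."): float(value)
            for key, value in header.items()
            if key.startswith("param.")
        }
    )
    initial = StateVector(
        **{
            key.removeprefix("initial."): float(value)
            for key, value in header.items()
            if key.startswith("initial.")
        }
    )
    spec = SimulationSpec(
        params=params,
        initial_state=initial,
        t_end=float(header["spec.t_end"]),
        dt=float(header["spec.dt"]),
        history_mode=_unquote(header["spec.history_mode"]),
        output_thin=int(header["spec.output_thin"]),
    )
    # %.17g renders whole numbers without a decimal point, so integral-looking
    # columns parse as int64; every trajectory column is a float quantity
    frame = read_table(path).astype(float)
    return Trajectory(
        frame=frame,
        clamp_events=int(header.get("clamp_events", 0)),
        spec=spec,
    )
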