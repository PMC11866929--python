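"""Plain-text file formats: RDF tables, extended XYZ, CSV traces.

RDF files are two whitespace-separated columns (bin center, intensity)
preceded by ``#`` comment lines carrying the grid metadata::

    # rdfbias RDF
    # n_bins = 80
    # delta = 0.05
    # r_lo = 0.0
    # weighting = identical
    0.025 0.0
    ...

Trajectories use extended XYZ: a per-frame comment line with
``Lattice="lx 0 0 0 ly 0 0 0 lz"`` and
``Properties=species:S:1:pos:R:3``, one atom per line.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .frames import Frame
from .grid import RDFGrid, RDFHistogram

__all__ = ["read_rdf_file", "write_rdf_file", "read_xyz", "write_xyz",
           "write_trace_csv", "read_trace_csv"]


def write_rdf_file(hist: RDFHistogram, path, weighting_mode: str = "identical") -> None:
    g = hist.grid
    lines = [
        "# rdfbias RDF",
        f"# n_bins = {g.n_bins}",
        f"# delta = {g.delta!r}",
        f"# r_lo = {g.r_lo!r}",
        f"# weighting = {weighting_mode}",
    ]
    for r, v in zip(g.centers, hist.values):
        lines.append(f"{float(r)!r} {float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


class RDFParseError(ValueError):
    pass


def read_rdf_file(path, grid: RDFGrid | None = None) -> RDFHistogram:
    """Read a two-column RDF table; validate spacing and optional metadata.

    If ``grid`` is given, the file's grid must match it exactly (a target
    file binned differently from the run configuration is a hard error).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rs, vs = [], []
    lines = path.read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        parts = line.split()
        if len(parts) != 2:
            raise RDFParseError(f"{path}:{ln}: expected two columns, got {len(parts)}")
        try:
            rs.append(float(parts[0]))
            vs.append(float(parts[1]))
        except ValueError:
            raise RDFParseError(f"{path}:{ln}: non-numeric row {line!r}") from None
    if not rs:
        raise RDFParseError(f"{path}: no data rows")
    if len(rs) < 2:
        raise RDFParseError(f"{path}: need at least two bins")
    r = np.asarray(rs)
    spacing = np.diff(r)
    delta = float(spacing.mean())
    if np.any(np.abs(spacing - delta) > 1e-9 * max(abs(delta), 1.0)):
        raise RDFParseError(f"{path}: bin centers are not uniformly spaced")
    r_lo = float(r[0] - 0.5 * delta)
    file_grid = RDFGrid(n_bins=len(rs), delta=delta, r_lo=max(r_lo, 0.0))
    for key, attr in (("n_bins", "n_bins"), ("delta", "delta"), ("r_lo", "r_lo")):
        if key in meta:
            stated = float(meta[key])
            actual = getattr(file_grid, attr)
            if not np.isclose(stated, actual, rtol=1e-9, atol=1e-12):
                raise RDFParseError(
                    f"{path}: metadata {key}={stated} disagrees with data ({actual})"
                )
    if grid is not None and file_grid != grid:
        raise RDFParseError(
            f"{path}: file grid (B={file_grid.n_bins}, delta={file_grid.delta}) "
            f"does not match the configured grid (B={grid.n_bins}, "
            f"delta={grid.delta})"
        )
    return RDFHistogram(file_grid, np.asarray(vs))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def write_xyz(frames, path, append: bool = False) -> None:
    """Write one frame or a list of frames as extended XYZ."""
    if isinstance(frames, Frame):
        frames = [frames]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for frame in frames:
            lx, ly, lz = (float(v) for v in frame.box)
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lx!r} 0.0 0.0 0.0 {ly!r} 0.0 0.0 0.0 {lz!r}" '
                f"Properties=species:S:1:pos:R:3 Time={float(frame.time)!r}\n"
            )
            for s, (x, y, z) in zip(frame.species, frame.positions):
                fh.write(f"{s} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path, wrap: bool = True) -> list[Frame]:
    """Read all frames of an extended-XYZ file.

    ``wrap=False`` keeps coordinates as stored (required for MSD input,
    where positions must stay unwrapped); the Frame container wraps on
    construction, so unwrapped trajectories are returned as raw arrays in
    ``frame.positions`` via a private bypass.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise ValueError(f"{path}:{k + 1}: expected atom count") from None
        comment = lines[k + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise ValueError(f"{path}:{k + 2}: missing Lattice specification")
        lat = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
        if np.any(lat - np.diag(np.diag(lat))):
            raise ValueError(f"{path}:{k + 2}: only orthorhombic lattices supported")
        box = np.diag(lat)
        tm = re.search(r"Time=([-\d.eE+]+)", comment)
        time = float(tm.group(1)) if tm else 0.0
        species, pos = [], []
        for row in lines[k + 2 : k + 2 + n]:
            parts = row.split()
            species.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        frame = Frame(np.asarray(pos), box, np.asarray(species, dtype=object), time)
        if not wrap:
            frame.positions = np.asarray(pos, dtype=float)
        frames.append(frame)
        k += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    return frames


def write_trace_csv(path, header: list[str], rows: np.ndarray) -> None:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    np.savetxt(path, rows, delimiter=",", header=",".join(header), comments="")


def read_trace_csv(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return header, data
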