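"""Grid file I/O: UHBD ASCII and OpenDX scalar dialects.

Both formats describe a node-centred, uniformly spaced lattice.  The UHBD
ASCII layout is the classic Fortran one (header records followed by
per-z-plane blocks, x fastest); the OpenDX dialect is the "regular
positions, regular connections" scalar field written by common
Poisson-Boltzmann solvers (z fastest).  Reads and writes round-trip origin,
spacing and dimensions exactly and values to better than 1e-6 relative.
"""

from __future__ import annotations

import numpy as np

from .grids import Grid3D

__all__ = ["read_grid", "write_grid", "GridParseError"]


class GridParseError(ValueError):
    """Malformed grid file; message names the offending line."""


def read_grid(path: str, format: str) -> Grid3D:
    if format == "uhbd":
        return _read_uhbd(path)
    if format == "dx":
        return _read_dx(path)
    raise GridParseError(f"unknown grid format {format!r}")


def write_grid(grid: Grid3D, path: str, format: str) -> None:
    if format == "uhbd":
        _write_uhbd(grid, path)
    elif format == "dx":
        _write_dx(grid, path)
    else:
        raise GridParseError(f"unknown grid format {format!r}")


# ---------------------------------------------------------------- UHBD ASCII


def _read_uhbd(path: str) -> Grid3D:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        # line 1: title; line 2: scale, dum, flags (ignored)
        header = lines[2].split()
        im, jm, km = int(header[0]), int(header[1]), int(header[2])
        h = float(header[3])
        ox, oy, oz = (float(v) for v in header[4:7])
    except (IndexError, ValueError) as exc:
        raise GridParseError(f"{path}: malformed UHBD header (line 3): {exc}") from exc
    # UHBD convention: node (1,1,1) sits at origin + h
    origin = np.array([ox, oy, oz]) + h
    values = np.empty((im, jm, km))
    ln = 5  # 0-based index of the first plane header (lines 4,5 are dummies)
    for _ in range(km):
        try:
            kk, im2, jm2 = (int(v) for v in lines[ln].split())
        except (IndexError, ValueError) as exc:
            raise GridParseError(f"{path}: bad plane header at line {ln + 1}") from exc
        if im2 != im or jm2 != jm or not (1 <= kk <= km):
            raise GridParseError(f"{path}: plane header at line {ln + 1} disagrees with grid dims")
        ln += 1
        need = im * jm
        plane = []
        while len(plane) < need:
            try:
                plane.extend(float(v) for v in lines[ln].split())
            except (IndexError, ValueError) as exc:
                raise GridParseError(f"{path}: bad value record at line {ln + 1}") from exc
            ln += 1
        if len(plane) != need:
            raise GridParseError(f"{path}: plane {kk} holds {len(plane)} values, expected {need}")
        # x fastest, then y
        values[:, :, kk - 1] = np.asarray(plane).reshape(jm, im).T
    return Grid3D(origin=origin, spacing=h, values=values, kind="potential")


def _fmt(vals, spec: str = ".9E") -> str:
    return " ".join(format(v, spec) for v in vals)


def _write_uhbd(grid: Grid3D, path: str) -> None:
    im, jm, km = grid.dims
    h = grid.spacing
    o = grid.origin - h
    with open(path, "w") as fh:
        fh.write("rigidbd grid".ljust(72) + "\n")
        fh.write(f"{_fmt([1.0, 0.0])} {1:7d}{0:7d}{km:7d}{1:7d}{km:7d}\n")
        # header floats use full precision so origin/spacing round-trip exactly
        fh.write(f"{im:7d}{jm:7d}{km:7d} {_fmt([h, o[0], o[1], o[2]], '.17g')}\n")
        fh.write(_fmt([0.0, 0.0, 0.0, 0.0]) + "\n")
        fh.write(f"{0:7d}{0:7d}\n")
        for k in range(km):
            fh.write(f"{k + 1:7d}{im:7d}{jm:7d}\n")
            plane = grid.values[:, :, k].T.ravel()  # x fastest
            for start in range(0, plane.size, 6):
                fh.write(_fmt(plane[start : start + 6]) + "\n")


# ------------------------------------------------------------------- OpenDX


def _read_dx(path: str) -> Grid3D:
    dims = None
    origin = None
    deltas = []
    n_items = None
    data: list[float] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "object":
                if "gridpositions" in tok:
                    try:
                        dims = tuple(int(v) for v in tok[-3:])
                    except ValueError as exc:
                        raise GridParseError(f"{path}:{ln}: bad gridpositions counts") from exc
                elif "array" in tok:
                    try:
                        n_items = int(tok[tok.index("items") + 1])
                    except (ValueError, IndexError) as exc:
                        raise GridParseError(f"{path}:{ln}: bad array item count") from exc
            elif tok[0] == "origin":
                origin = np.array([float(v) for v in tok[1:4]])
            elif tok[0] == "delta":
                deltas.append([float(v) for v in tok[1:4]])
            elif tok[0] in ("attribute", "component"):
                continue
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(v) for v in tok)
                except ValueError as exc:
                    raise GridParseError(f"{path}:{ln}: bad data value") from exc
    if dims is None or origin is None or len(deltas) != 3:
        raise GridParseError(f"{path}: incomplete DX header")
    d = np.asarray(deltas)
    if not np.allclose(d, np.diag(np.diag(d))) or not np.allclose(np.diag(d), d[0][0]):
        raise GridParseError(f"{path}: only isotropic axis-aligned DX grids are supported")
    if n_items is None or len(data) != n_items or n_items != int(np.prod(dims)):
        raise GridParseError(f"{path}: value count {len(data)} does not match dims {dims}")
    values = np.asarray(data).reshape(dims)  # z fastest == C order for (nx,ny,nz)
    return Grid3D(origin=origin, spacing=float(d[0][0]), values=values, kind="potential")


def _write_dx(grid: Grid3D, path: str) -> None:
    nx, ny, nz = grid.dims
    h = grid.spacing
    o = grid.origin
    flat = grid.values.ravel()  # z fastest
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar grid written by rigidbd\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.17g} {o[1]:.17g} {o[2]:.17g}\n")
        fh.write(f"delta {h:.17g} 0 0\n")
        fh.write(f"delta 0 {h:.17g} 0\n")
        fh.write(f"delta 0 0 {h:.17g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} data follows\n")
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.9e}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
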