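"""Whitespace-delimited HILLS / COLVAR / FES text I/O (PLUMED dialect).

Files carry a ``#! FIELDS ...`` header naming the columns; further ``#!``
lines are treated as comments. Floats are written with ``repr`` so that
read(write(x)) round-trips bit-exactly.

HILLS layout:   time <cvs...> sigma_<cv>... height biasf
COLVAR layout:  time <cvs...> [extra columns...]
FES layout:     <cvs...> free_energy mask
"""

from __future__ import annotations

import numpy as np

from .bias import BiasPotential, Hill
from .errors import ParseError, ValidationError
from .grids import FreeEnergySurface, GridSpec
from .trajectory import CVTrajectory


def _fmt(x: float) -> str:
    return repr(float(x))


def _read_table(path):
    """Parse a FIELDS-headed table; returns (field names, rows, row line numbers)."""
    fields = None
    rows = []
    linenos = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                toks = line[2:].split()
                if toks and toks[0] == "FIELDS":
                    if fields is not None:
                        raise ParseError("duplicate FIELDS header", path, lineno)
                    fields = toks[1:]
                continue
            if line.startswith("#"):
                continue
            if fields is None:
                raise ParseError("data before '#! FIELDS' header", path, lineno)
            cells = line.split()
            if len(cells) != len(fields):
                raise ParseError(
                    f"expected {len(fields)} columns, found {len(cells)}", path, lineno
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"non-numeric cell: {exc}", path, lineno) from None
            linenos.append(lineno)
    if fields is None:
        raise ParseError("missing '#! FIELDS' header", path)
    return fields, np.array(rows, dtype=float).reshape(len(rows), len(fields)), linenos


# ---------------------------------------------------------------------------
# HILLS


def write_hills(path, bias: BiasPotential, cv_names) -> None:
    cv_names = tuple(cv_names)
    if len(cv_names) != bias.ndim:
        raise ValidationError("write_hills: cv_names length mismatch")
    times, centers, widths, heights, biasf = bias.arrays()
    with open(path, "w") as fh:
        cols = (
            ["time"]
            + list(cv_names)
            + [f"sigma_{n}" for n in cv_names]
            + ["height", "biasf"]
        )
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        fh.write("# heights are post-tempering (PLUMED HEIGHT convention)\n")
        for k in range(len(times)):
            row = (
                [times[k]]
                + list(centers[k])
                + list(widths[k])
                + [heights[k], biasf[k]]
            )
            fh.write(" ".join(_fmt(x) for x in row) + "\n")


def read_hills(path, periodic=None, domain=None) -> BiasPotential:
    """Read a HILLS file into a BiasPotential; returns it with ``cv_names`` set."""
    fields, data, linenos = _read_table(path)
    if not fields or fields[0] != "time":
        raise ParseError("first HILLS field must be 'time'", path)
    try:
        nsig = [f.startswith("sigma_") for f in fields].index(True)
    except ValueError:
        raise ParseError("no sigma_<cv> fields in HILLS header", path) from None
    cv_names = tuple(fields[1:nsig])
    ndim = len(cv_names)
    if ndim == 0:
        raise ParseError("no CV fields between 'time' and sigma columns", path)
    expected = (
        ["time"] + list(cv_names) + [f"sigma_{n}" for n in cv_names] + ["height", "biasf"]
    )
    if fields != expected:
        raise ParseError(
            f"unexpected HILLS layout {fields}; expected {expected}", path
        )
    bias = BiasPotential(ndim, periodic=periodic, domain=domain)
    for i in range(len(data)):
        row = data[i]
        if i and row[ndim * 2 + 2] != data[0][ndim * 2 + 2]:
            raise ParseError("inconsistent biasf across rows", path, linenos[i])
        try:
            bias.append(
                Hill(
                    time=row[0],
                    center=row[1 : 1 + ndim],
                    widths=row[1 + ndim : 1 + 2 * ndim],
                    height=row[1 + 2 * ndim],
                    bias_factor=row[2 + 2 * ndim],
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), path, linenos[i]) from None
    bias.cv_names = cv_names
    return bias


# ---------------------------------------------------------------------------
# COLVAR


def write_colvar(path, traj: CVTrajectory) -> None:
    extras = list(traj.extras)
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(list(traj.cv_names) + extras) + "\n")
        for i in range(len(traj)):
            row = [traj.times[i]] + list(traj.points[i]) + [
                traj.extras[k][i] for k in extras
            ]
            fh.write(" ".join(_fmt(x) for x in row) + "\n")


def read_colvar(path, n_cv=None, replica_id=None) -> CVTrajectory:
    """Read a COLVAR file.

    ``n_cv`` fixes how many leading columns after ``time`` are collective
    variables; columns beyond that are preserved as extras. By default every
    column is treated as a CV.
    """
    fields, data, linenos = _read_table(path)
    if not fields or fields[0] != "time":
        raise ParseError("first COLVAR field must be 'time'", path)
    names = fields[1:]
    if not names:
        raise ParseError("COLVAR has no CV columns", path)
    if n_cv is None:
        n_cv = len(names)
    if n_cv < 1 or n_cv > len(names):
        raise ValidationError(f"read_colvar: n_cv={n_cv} out of range")
    if len(data) == 0:
        raise ParseError("COLVAR contains no data rows", path)
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 1
        raise ParseError("times not strictly increasing", path, linenos[bad])
    extras = {
        name: data[:, 1 + n_cv + j] for j, name in enumerate(names[n_cv:])
    }
    return CVTrajectory(
        times,
        data[:, 1 : 1 + n_cv],
        replica_id=str(replica_id) if replica_id is not None else "0",
        cv_names=tuple(names[:n_cv]),
        extras=extras,
    )


# ---------------------------------------------------------------------------
# FES grid tables


def write_fes(path, fes: FreeEnergySurface, cv_names) -> None:
    cv_names = tuple(cv_names)
    grid = fes.grid
    if len(cv_names) != grid.ndim:
        raise ValidationError("write_fes: cv_names length mismatch")
    pts = grid.points()
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cv_names) + " free_energy mask\n")
        fh.write(
            "#! GRID "
            + " ".join(
                f"{n}:{lo}:{hi}:{int(per)}"
                for n, lo, hi, per in zip(
                    grid.n_bins, grid.mins, grid.maxs, grid.periodic
                )
            )
            + "\n"
        )
        F = fes.F.ravel()
        m = fes.mask.ravel()
        for i in range(len(pts)):
            fh.write(
                " ".join(_fmt(x) for x in pts[i])
                + f" {_fmt(F[i])} {int(m[i])}\n"
            )


def read_fes(path) -> FreeEnergySurface:
    fields = None
    gridline = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#! FIELDS"):
                fields = line.split()[2:]
            elif line.startswith("#! GRID"):
                gridline = line.split()[2:]
            if fields and gridline:
                break
    if fields is None or gridline is None:
        raise ParseError("FES file needs '#! FIELDS' and '#! GRID' headers", path)
    nb, mins, maxs, per = [], [], [], []
    for tok in gridline:
        n, lo, hi, p = tok.split(":")
        nb.append(int(n))
        mins.append(float(lo))
        maxs.append(float(hi))
        per.append(bool(int(p)))
    grid = GridSpec(tuple(mins), tuple(maxs), tuple(nb), tuple(per))
    tab_fields, data, _ = _read_table(path)
    if tab_fields[-2:] != ["free_energy", "mask"]:
        raise ParseError("FES table must end with free_energy and mask columns", path)
    if len(data) != grid.size:
        raise ParseError(
            f"FES table has {len(data)} rows, grid declares {grid.size}", path
        )
    F = data[:, -2].reshape(grid.shape)
    mask = data[:, -1].astype(bool).reshape(grid.shape)
    return FreeEnergySurface(grid, F, mask)
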