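"""xyz-style plain-text I/O for molecular fixture frames.

Per frame: a particle-count line, a comment line carrying the box lengths,
tagged/neighbor index lists and the reference geometry, then one particle
per line (``element x y z``; tagged particles are ``B``, neighbours ``N``).
"""

from __future__ import annotations

import json

import numpy as np

from .cv import MolecularFrame
from .errors import ParseError


def write_xyz_frames(path, frames) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            meta = {
                "box": list(frame.box),
                "biased": list(frame.biased_indices),
                "neighbors": list(frame.neighbor_indices),
                "reference_point": frame.reference_point.tolist(),
                "reference_axis": frame.reference_axis.tolist(),
                "plane_normal": frame.plane_normal.tolist(),
            }
            fh.write(f"{len(frame.coordinates)}\n")
            fh.write(json.dumps(meta) + "\n")
            tagged = set(frame.biased_indices)
            for i, xyz in enumerate(frame.coordinates):
                el = "B" if i in tagged else "N"
                fh.write(
                    f"{el} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n"
                )


def read_xyz_frames(path):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected particle-count line", path, i + 1) from None
        try:
            meta = json.loads(lines[i + 1])
        except (IndexError, json.JSONDecodeError):
            raise ParseError("bad frame comment line", path, i + 2) from None
        coords = []
        for k in range(n):
            try:
                parts = lines[i + 2 + k].split()
                coords.append([float(x) for x in parts[1:4]])
            except (IndexError, ValueError):
                raise ParseError("bad particle line", path, i + 3 + k) from None
        frames.append(
            MolecularFrame(
                np.array(coords),
                tuple(meta["biased"]),
                tuple(meta["neighbors"]),
                np.array(meta["reference_point"]),
                np.array(meta["reference_axis"]),
                np.array(meta["plane_normal"]),
                tuple(meta["box"]),
            )
        )
        i += 2 + n
    return frames
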