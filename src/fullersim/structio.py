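"""Structure file I/O: XYZ (single and multi-frame) and PDB with CONECT.

Thin, strict readers/writers.  Coordinates are written with 6 decimals;
malformed input raises :class:`StructureParseError` carrying the
offending line number.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "StructureParseError",
    "write_xyz",
    "read_xyz",
    "write_xyz_frames",
    "read_xyz_frames",
    "write_pdb",
    "read_pdb",
]


class StructureParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _format_xyz_frame(positions, elements, comment) -> str:
    lines = [str(len(positions)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(elements, positions):
        lines.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    return "\n".join(lines) + "\n"


def write_xyz(path, positions, elements=None, comment: str = "") -> None:
    positions = np.asarray(positions, float)
    if elements is None:
        elements = ["C"] * len(positions)
    with open(path, "w") as fh:
        fh.write(_format_xyz_frame(positions, elements, comment))


def write_xyz_frames(path, frames, elements=None, comments=None) -> None:
    """Multi-frame (trajectory) XYZ."""
    frames = [np.asarray(f, float) for f in frames]
    if elements is None:
        elements = ["C"] * len(frames[0])
    with open(path, "w") as fh:
        for k, f in enumerate(frames):
            comment = comments[k] if comments is not None else f"frame {k}"
            fh.write(_format_xyz_frame(f, elements, comment))


def _read_xyz_stream(path, lines, start):
    try:
        n = int(lines[start].strip())
    except (IndexError, ValueError):
        raise StructureParseError(path, start + 1, "expected an atom count")
    if start + 1 >= len(lines):
        raise StructureParseError(path, start + 2, "missing comment line")
    comment = lines[start + 1].rstrip("\n")
    elements, coords = [], []
    for k in range(n):
        ln = start + 2 + k
        if ln >= len(lines):
            raise StructureParseError(path, ln + 1, "truncated atom block")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise StructureParseError(path, ln + 1, "expected 'element x y z'")
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise StructureParseError(path, ln + 1, "non-numeric coordinate")
        elements.append(parts[0])
    return elements, np.array(coords), comment, start + 2 + n


def read_xyz(path):
    """Returns ``(elements, positions, comment)`` of the first frame."""
    with open(path) as fh:
        lines = fh.readlines()
    elements, coords, comment, _ = _read_xyz_stream(path, lines, 0)
    return elements, coords, comment


def read_xyz_frames(path):
    """Returns ``(elements, list_of_position_arrays, comments)``."""
    with open(path) as fh:
        lines = fh.readlines()
    pos, comments, elements = [], [], None
    at = 0
    while at < len(lines) and lines[at].strip():
        elements, coords, comment, at = _read_xyz_stream(path, lines, at)
        pos.append(coords)
        comments.append(comment)
    return elements, pos, comments


def write_pdb(path, positions, bonds, elements=None, title: str = "") -> None:
    """HETATM records plus CONECT records for every bond."""
    positions = np.asarray(positions, float)
    n = len(positions)
    if elements is None:
        elements = ["C"] * n
    neighbors: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    with open(path, "w") as fh:
        if title:
            fh.write(f"TITLE     {title}\n")
        for i, (el, (x, y, z)) in enumerate(zip(elements, positions), start=1):
            fh.write(
                f"HETATM{i:5d} {el:>2s}   FUL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        for i in range(n):
            nb = sorted(neighbors[i])
            for k in range(0, len(nb), 4):
                row = "".join(f"{j + 1:5d}" for j in nb[k:k + 4])
                fh.write(f"CONECT{i + 1:5d}{row}\n")
        fh.write("END\n")


def read_pdb(path):
    """Returns ``(elements, positions, bonds)``; bonds from CONECT."""
    elements, coords = [], []
    bonds: set[tuple[int, int]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("HETATM", "ATOM  "):
                try:
                    coords.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError:
                    raise StructureParseError(path, ln, "malformed coordinate field")
                elements.append(line[76:78].strip() or line[12:14].strip())
            elif rec == "CONECT":
                fields = line[6:].split()
                if not fields:
                    raise StructureParseError(path, ln, "empty CONECT record")
                try:
                    idx = [int(v) - 1 for v in fields]
                except ValueError:
                    raise StructureParseError(path, ln, "non-integer CONECT field")
                for j in idx[1:]:
                    bonds.add(tuple(sorted((idx[0], j))))
    return elements, np.array(coords), sorted(bonds)
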