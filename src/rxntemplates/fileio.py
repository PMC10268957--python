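"""Plain-text structure input: XYZ coordinate files plus bond lists.

Molecular graphs are built from a standard ``.xyz`` file (count line,
comment line, ``element x y z`` records) paired with a bond file holding
one whitespace-separated ``i j order`` triple per line (0-based).  The
coordinates themselves are discarded — only elements and connectivity
enter the graph — and an edge exists when the supplied bond order is at
least 0.5.  No bond perception from distances is attempted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .molgraph import GraphError, MolecularGraph, build_graph

__all__ = ["read_xyz", "read_bond_file", "graph_from_xyz"]

BOND_ORDER_EDGE_MIN = 0.5


def read_xyz(path: Union[str, Path]) -> list[str]:
    """Element symbols from a standard XYZ file (geometry ignored)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GraphError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GraphError(f"{path}: first line must be the atom count")
    records = [l for l in lines[2:2 + count]]
    if len(records) < count:
        raise GraphError(f"{path}: expected {count} atom records, "
                         f"found {len(records)}")
    elements = []
    for k, line in enumerate(records):
        parts = line.split()
        if len(parts) < 4:
            raise GraphError(f"{path}, atom {k}: malformed record {line!r}")
        elements.append(parts[0])
    return elements


def read_bond_file(path: Union[str, Path]) -> list[tuple[int, int, float]]:
    """Bond triples ``(i, j, order)`` from a plain bond list file."""
    triples = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise GraphError(f"{path}, line {ln}: expected 'i j order', "
                             f"got {line!r}")
        triples.append((int(parts[0]), int(parts[1]), float(parts[2])))
    return triples


def graph_from_xyz(xyz_path: Union[str, Path],
                   bond_path: Union[str, Path],
                   charge: int = 0) -> MolecularGraph:
    """Build a molecular graph from an XYZ file and its bond list."""
    elements = read_xyz(xyz_path)
    bonds = [(i, j) for i, j, order in read_bond_file(bond_path)
             if order >= BOND_ORDER_EDGE_MIN]
    return build_graph(elements, bonds, charge=charge)
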