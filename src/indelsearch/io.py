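"""Structure input/output and database assembly.

Structures enter the tool either as PDB/mmCIF files — from which the
C-alpha trace of each polypeptide chain is taken as the coordinate
sequence — or as plain whitespace-delimited xyz tables (one residue per
line, ``#`` comments allowed).  A multi-structure database is represented
by concatenating all chains into one long text chain and remembering the
boundaries, so the search can run once over the concatenation while
discarding matches that would cross from one structure into the next.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .core_geometry import Chain

logger = logging.getLogger(__name__)

__all__ = ["StructureDatabase", "read_pdb_calpha", "read_xyz", "write_xyz", "load_structures"]


@dataclass(frozen=True)
class StructureDatabase:
    """An ordered collection of chains plus their concatenation.

    ``starts[idx]`` is the 0-based offset of chain ``idx`` inside
    ``concatenated``; a window of the concatenated text is a valid match
    window only if it lies entirely within one source chain.
    """

    ids: tuple[str, ...]
    chains: tuple[Chain, ...]
    concatenated: Chain
    starts: tuple[int, ...]

    @classmethod
    def from_chains(cls, chains: Iterable[Chain], ids: Iterable[str] | None = None) -> "StructureDatabase":
        chains = tuple(chains)
        if not chains:
            raise ValueError("database needs at least one chain")
        if ids is None:
            ids = tuple(
                ch.label if ch.label else f"structure_{idx + 1}" for idx, ch in enumerate(chains)
            )
        else:
            ids = tuple(ids)
            if len(ids) != len(chains):
                raise ValueError("one identifier per chain required")
        starts = []
        off = 0
        for ch in chains:
            starts.append(off)
            off += len(ch)
        concatenated = Chain(np.vstack([ch.coords for ch in chains]), "database")
        return cls(ids=ids, chains=chains, concatenated=concatenated, starts=tuple(starts))

    def __len__(self) -> int:
        return len(self.chains)

    def items(self) -> Iterator[tuple[str, Chain]]:
        return iter(zip(self.ids, self.chains))

    def segment_of_position(self, position: int) -> tuple[str, int, int] | None:
        """Source structure containing a 1-based concatenated position.

        Returns ``(identifier, first, last)`` with 1-based inclusive global
        bounds of that structure, or None if out of range.
        """
        if not 1 <= position <= len(self.concatenated):
            return None
        idx = bisect_right(self.starts, position - 1) - 1
        first = self.starts[idx] + 1
        last = self.starts[idx] + len(self.chains[idx])
        return self.ids[idx], first, last


def _calpha_of_residue(residue):
    """Pick the single C-alpha atom of a residue, resolving altlocs.

    Disordered atoms are resolved by highest occupancy, ties by altloc
    identifier (so 'A' wins over 'B').
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = children[0]
    return atom


def read_pdb_calpha(
    path: str | Path,
    chains: Iterable[str] | None = None,
    model: int | None = None,
) -> list[tuple[str, Chain]]:
    """C-alpha coordinate sequences of the polypeptide chains in a file.

    Reads PDB (or mmCIF, by extension) through Bio.PDB.  Only ATOM records
    are used (HETATM residues are skipped), the first model is taken unless
    ``model`` gives a serial number, residues keep file order (insertion
    codes included), and alternate locations resolve to the highest
    occupancy.  Chains without any C-alpha atom are dropped with a warning.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")
    if model is None:
        selected = models[0]
    else:
        matching = [mdl for mdl in models if mdl.serial_num == model or mdl.id == model]
        if not matching:
            raise ValueError(f"model {model} not found in {path}")
        selected = matching[0]
    wanted = set(chains) if chains is not None else None
    out: list[tuple[str, Chain]] = []
    for chain in selected:
        if wanted is not None and chain.id not in wanted:
            continue
        coords = []
        for residue in chain:
            hetfield = residue.id[0]
            if hetfield.strip():  # HETATM / water
                continue
            atom = _calpha_of_residue(residue)
            if atom is not None:
                coords.append(atom.get_coord())
        if not coords:
            logger.warning("chain %s of %s has no C-alpha atoms; skipped", chain.id, path.name)
            continue
        out.append((chain.id, Chain(np.asarray(coords, dtype=float), chain.id)))
    if not out:
        logger.warning("no C-alpha coordinates found in %s", path)
    return out


def read_xyz(path: str | Path) -> Chain:
    """One chain from a whitespace-delimited ``x y z`` table.

    Blank lines and ``#`` comments are ignored; any other malformed line is
    an error reported with its line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {len(fields)}")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no coordinates found (chain must have length >= 1)")
    return Chain(np.asarray(rows), path.stem)


def write_xyz(chain: Chain, path: str | Path) -> None:
    """Write a 3-D chain as an xyz table at full double precision.

    ``repr`` of each float is used, so write-then-read is the identity.
    """
    if chain.dim != 3:
        raise ValueError("xyz output is defined for 3-D chains only")
    with open(path, "w") as fh:
        for x, y, z in chain.coords:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def load_structures(path: str | Path, fmt: str = "auto") -> list[tuple[str, Chain]]:
    """Dispatch a structure file to the right reader.

    ``fmt`` is ``pdb``, ``xyz`` or ``auto`` (by extension; xyz-like
    extensions and unknown ones are treated as xyz tables).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "pdb" if path.suffix.lower() in {".pdb", ".ent", ".cif", ".mmcif"} else "xyz"
    if fmt == "pdb":
        return read_pdb_calpha(path)
    if fmt == "xyz":
        chain = read_xyz(path)
        return [(chain.label, chain)]
    raise ValueError(f"unknown structure format {fmt!r}")
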