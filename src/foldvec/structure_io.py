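"""Reading and writing macromolecular structures as CA traces.

PDB and mmCIF files are parsed with gemmi; each polymer chain is reduced to
the ordered list of residues that possess an alpha-carbon atom.  Residues
without a CA are dropped rather than imputed, alternate locations are
resolved to the highest-occupancy conformer (first encountered on ties),
and insertion-coded residues keep their author order.  Output is CA-only
PDB, which round-trips coordinates to the format's fixed-width precision
(1e-3 Angstrom).

Label metadata travels separately as TSV with columns
``id, fold, superfamily, family, topologies`` (topologies comma-separated).
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .structures import AssemblyStructure, ChainStructure, one_to_three, three_to_one


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


class EmptyStructureError(ValueError):
    """Raised when no chain with at least one CA atom is present."""


def _read_gemmi(path: str, format: str) -> gemmi.Structure:
    try:
        if format == "pdb":
            return gemmi.read_pdb(path)
        if format == "mmcif":
            doc = gemmi.cif.read(path)
            return gemmi.make_structure_from_block(doc.sole_block())
        if format == "auto":
            return gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path!r} as {format}: {exc}") from exc
    raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")


def _best_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA among altlocs; first encountered wins ties."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name not in ("C", ""):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_structure(path: str, format: str = "auto") -> AssemblyStructure:
    """Read a structure file into an assembly of CA-trace chains.

    Parameters
    ----------
    path : str
        Path to a PDB or mmCIF file.
    format : {"pdb", "mmcif", "auto"}
        Dialect; ``auto`` detects from the file content/extension.

    Returns
    -------
    AssemblyStructure
        One :class:`ChainStructure` per polymer chain with >= 1 CA atom,
        residues in author order.

    Raises
    ------
    StructureFormatError
        If the file does not parse under the named dialect.
    EmptyStructureError
        If no chain contributes a CA atom.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise EmptyStructureError(f"{path!r}: no models")
    model = st[0]
    entry_id = st.name or os.path.splitext(os.path.basename(path))[0]

    chains = []
    for chain in model:
        coords, seq = [], []
        for residue in chain:
            ca = _best_ca(residue)
            if ca is None:
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            seq.append(three_to_one(residue.name))
        if coords:
            chains.append(
                ChainStructure(
                    chain_id=chain.name,
                    sequence="".join(seq),
                    ca_coords=np.asarray(coords, dtype=float),
                    source=f"{entry_id}:{chain.name}",
                )
            )
    if not chains:
        raise EmptyStructureError(f"{path!r}: no chain with a CA atom")
    return AssemblyStructure(assembly_id=entry_id, chains=chains)


def write_structure(assembly: AssemblyStructure, path: str, format: str = "pdb") -> None:
    """Write an assembly as a CA-only PDB file.

    Coordinates survive a read/write round trip within 1e-3 Angstrom
    (the PDB fixed-width coordinate precision).

    Raises
    ------
    ValueError
        If a chain exceeds the PDB residue-numbering capacity (9999).
    """
    if format != "pdb":
        raise ValueError(f"unsupported output format {format!r}; only 'pdb'")
    st = gemmi.Structure()
    st.name = assembly.assembly_id
    model = gemmi.Model("1")
    for chain_struct in assembly.chains:
        if len(chain_struct) > 9999:
            raise ValueError(
                f"chain {chain_struct.chain_id!r} has {len(chain_struct)} residues;"
                " PDB residue numbering supports at most 9999"
            )
        chain = gemmi.Chain(chain_struct.chain_id)
        for i, (code, xyz) in enumerate(
            zip(chain_struct.sequence, chain_struct.ca_coords), start=1
        ):
            res = gemmi.Residue()
            res.name = one_to_three(code)
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(path)


def write_labels(structures, path: str) -> None:
    """Write a label-metadata TSV for a collection of labelled chains."""
    rows = []
    for s in structures:
        rows.append(
            {
                "id": s.source or s.chain_id,
                "fold": s.labels.get("fold", ""),
                "superfamily": s.labels.get("superfamily", ""),
                "family": s.labels.get("family", ""),
                "topologies": ",".join(s.labels.get("topologies", ())),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(path: str) -> pd.DataFrame:
    """Read a label-metadata TSV into a DataFrame indexed by structure id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "fold", "superfamily", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table {path!r} missing columns {sorted(missing)}")
    return df.set_index("id")
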