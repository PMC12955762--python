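"""Core in-memory containers for CA-trace chains and multimeric assemblies.

The whole toolkit operates on alpha-carbon traces: a chain is an ordered
sequence of residues, each contributing one CA coordinate.  Labels attach
classification metadata (fold / superfamily / family, or a list of domain
topologies) used by the benchmark statistics; they are carried but never
interpreted geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: one-letter codes for the 20 standard amino acids, in a fixed order used
#: by the residue-type embedding of the geometric encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(resname: str) -> str:
    """Map a three-letter residue name to a one-letter code ('X' if unknown)."""
    return _THREE_TO_ONE.get(resname.upper(), "X")


def one_to_three(code: str) -> str:
    """Map a one-letter residue code to a three-letter name (UNK if unknown)."""
    return _ONE_TO_THREE.get(code.upper(), "UNK")


@dataclass
class ChainStructure:
    """One polypeptide chain as an ordered CA trace.

    Parameters
    ----------
    chain_id : str
        Author chain identifier.
    sequence : str
        One-letter residue codes, one per CA coordinate.
    ca_coords : (L, 3) ndarray
        CA coordinates in Angstrom, residue order.
    labels : dict, optional
        Classification metadata; recognised keys are ``fold``,
        ``superfamily``, ``family`` and ``topologies`` (a tuple of strings).
    source : str, optional
        File or entry identifier for provenance.
    """

    chain_id: str
    sequence: str
    ca_coords: np.ndarray
    labels: dict = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (L, 3) array")
        L = self.ca_coords.shape[0]
        if L < 1:
            raise ValueError("chain must contain at least one residue")
        if len(self.sequence) != L:
            raise ValueError(
                f"sequence length {len(self.sequence)} != coordinate rows {L}"
            )
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite CA coordinate")
        if L > 1:
            steps = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
            if np.any(steps <= 0.0):
                raise ValueError("duplicated consecutive CA coordinates")

    def __len__(self) -> int:
        return self.ca_coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        """Return a rigidly moved copy: ``x -> x @ R.T + t``."""
        return ChainStructure(
            chain_id=self.chain_id,
            sequence=self.sequence,
            ca_coords=self.ca_coords @ np.asarray(rotation).T + np.asarray(translation),
            labels=dict(self.labels),
            source=self.source,
        )

    def __eq__(self, other) -> bool:  # value semantics, used by determinism tests
        if not isinstance(other, ChainStructure):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.sequence == other.sequence
            and np.array_equal(self.ca_coords, other.ca_coords)
            and self.labels == other.labels
        )


@dataclass
class AssemblyStructure:
    """An ordered collection of chains forming one multimeric assembly."""

    assembly_id: str
    chains: list

    def __post_init__(self) -> None:
        if len(self.chains) < 1:
            raise ValueError("assembly must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in assembly: {ids}")

    def __len__(self) -> int:
        return len(self.chains)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chains)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssemblyStructure):
            return NotImplemented
        return (
            self.assembly_id == other.assembly_id
            and len(self.chains) == len(other.chains)
            and all(a == b for a, b in zip(self.chains, other.chains))
        )
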