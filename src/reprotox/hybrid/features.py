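"""SMILES tokenization and molecular-graph construction for the hybrid model.

Tokenization is atom-aware: bracket atoms and two-letter elements (Cl, Br)
are single tokens, as are ring-closure digits and bond symbols.  Graphs carry
one node per heavy atom with element/degree/charge/aromaticity/H-count
features and both directed edges per bond.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from ..standardize import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = ["TokenSeq", "MolGraph", "smiles_tokens", "build_vocab",
           "tokenize_smiles", "detokenize", "smiles_to_graph",
           "pad_graph_batch", "PAD_ID", "UNK_ID", "ATOM_FEATURE_DIM"]

_TOKEN_RE = re.compile(
    r"\[[^\]]+\]|Br|Cl|@@|@|%\d{2}|\d|[A-Za-z]|[=#+\-()/\\.$:~*]"
)

PAD_ID = 0
UNK_ID = 1
_SPECIALS = ("<pad>", "<unk>")


@dataclass(frozen=True)
class TokenSeq:
    """A tokenized, padded SMILES with its padding mask and vocabulary."""

    token_ids: np.ndarray      # (max_len,) int
    mask: np.ndarray           # (max_len,) uint8, 1 at real tokens
    vocab: dict
    max_len: int
    n_real: int
    truncated: bool = False


def smiles_tokens(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


def build_vocab(smiles_list) -> dict:
    """Token-to-id map over a corpus, with <pad>=0 and <unk>=1."""
    seen = set()
    for s in smiles_list:
        seen.update(smiles_tokens(s))
    vocab = {tok: i for i, tok in enumerate(_SPECIALS)}
    for tok in sorted(seen):
        vocab[tok] = len(vocab)
    return vocab


def tokenize_smiles(smiles: str, vocab: dict, max_len: int) -> TokenSeq:
    """Tokenize and pad one SMILES; out-of-vocabulary tokens map to <unk>."""
    tokens = smiles_tokens(smiles)
    truncated = len(tokens) > max_len
    if truncated:
        logger.info("SMILES truncated from %d to %d tokens", len(tokens), max_len)
        tokens = tokens[:max_len]
    ids = np.full(max_len, PAD_ID, dtype=np.intp)
    mask = np.zeros(max_len, dtype=np.uint8)
    for i, t in enumerate(tokens):
        ids[i] = vocab.get(t, UNK_ID)
        mask[i] = 1
    return TokenSeq(token_ids=ids, mask=mask, vocab=vocab, max_len=max_len,
                    n_real=len(tokens), truncated=truncated)


def detokenize(seq: TokenSeq) -> str:
    """Recover the SMILES of an in-vocabulary, untruncated token sequence."""
    inv = {i: t for t, i in seq.vocab.items()}
    return "".join(inv[int(i)] for i in seq.token_ids[:seq.n_real])


# ------------------------------------------------------------------- graphs

_ELEMENTS = (6, 7, 8, 16, 15, 9, 17, 35, 53)  # C N O S P F Cl Br I
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + 6 + 1 + 1 + 5  # = 23


@dataclass(frozen=True)
class MolGraph:
    """Dense molecular graph: heavy atoms as nodes, bonds as directed edges."""

    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    edges: np.ndarray          # (2E, 2) directed pairs, both directions
    bond_features: np.ndarray  # (2E, 5): order one-hot (1, arom, 2, 3) + ring

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    def adjacency(self, include_self_loops: bool = True) -> np.ndarray:
        n = self.n_atoms
        adj = np.zeros((n, n), dtype=np.float64)
        for i, j in self.edges:
            adj[i, j] = 1.0
        if include_self_loops:
            adj[np.diag_indices(n)] = 1.0
        return adj


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FEATURE_DIM)
    z = atom.GetAtomicNum()
    f[_ELEMENTS.index(z) if z in _ELEMENTS else len(_ELEMENTS)] = 1.0
    deg = min(atom.GetDegree(), 5)
    f[len(_ELEMENTS) + 1 + deg] = 1.0
    f[len(_ELEMENTS) + 7] = float(atom.GetFormalCharge())
    f[len(_ELEMENTS) + 8] = float(atom.GetIsAromatic())
    h = min(atom.GetTotalNumHs(), 4)
    f[len(_ELEMENTS) + 9 + h] = 1.0
    return f


_BOND_ORDER_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.AROMATIC: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


def smiles_to_graph(record) -> MolGraph:
    """Convert a standardized molecule to its dense graph representation."""
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, Chem.Mol):
        mol = record
    else:
        mol = Chem.MolFromSmiles(str(record))
    if mol is None:
        raise ValueError(f"invalid molecule: {record!r}")
    atoms = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    edges, bonds = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bf = np.zeros(5)
        bf[_BOND_ORDER_INDEX.get(b.GetBondType(), 0)] = 1.0
        bf[4] = float(b.IsInRing())
        for (u, v) in ((i, j), (j, i)):
            edges.append((u, v))
            bonds.append(bf)
    edges_arr = (np.array(edges, dtype=np.intp) if edges
                 else np.zeros((0, 2), dtype=np.intp))
    bonds_arr = np.array(bonds) if bonds else np.zeros((0, 5))
    return MolGraph(atom_features=atoms, edges=edges_arr, bond_features=bonds_arr)


def pad_graph_batch(graphs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense-pad graphs to a common size.

    Returns (features (B,N,f), adjacency-with-self-loops (B,N,N),
    node mask (B,N)); padded rows have zero features, no edges, mask 0.
    """
    n_max = max(g.n_atoms for g in graphs)
    B = len(graphs)
    feats = np.zeros((B, n_max, ATOM_FEATURE_DIM))
    adj = np.zeros((B, n_max, n_max))
    mask = np.zeros((B, n_max))
    for b, g in enumerate(graphs):
        n = g.n_atoms
        feats[b, :n] = g.atom_features
        adj[b, :n, :n] = g.adjacency()
        mask[b, :n] = 1.0
    return feats, adj, mask
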