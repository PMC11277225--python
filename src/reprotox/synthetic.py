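"""Deterministic synthetic molecules and descriptor tables for benchmarking.

Molecules are assembled from a small fragment grammar (alkyl / cycloalkyl /
aryl scaffolds with substituents) so that every output is a valid,
standardizable SMILES.  Class-1 ("toxic") molecules carry at least one of
three recognizable substructural motifs — a nitroaromatic, a phenolic
hydroxyl, or an aromatic ortho-diester (phthalate-like) — while class-0
molecules are built from a motif-free fragment pool.  Label noise flips the
structure/label correspondence with a given probability, which makes the
motif-label signal tunable down to chance.

Descriptor tables are generated column-by-column with an exactly realized
zero fraction and a Shannon entropy (10 equal-width bins) within +-0.1 bits
of target, so the two-stage descriptor filter can be checked against a
predicted keep/drop set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import shannon_entropy
from .standardize import MoleculeRecord, Rejection, standardize_record

__all__ = ["SynthSpec", "TOXIC_MOTIFS", "gen_toy_molecules",
           "gen_descriptor_table"]

# SMARTS patterns enriched in class 1, echoing the three archetypes
# (hydantoin-like/nitroaromatic, phenolic, phthalate-ester chemotypes)
TOXIC_MOTIFS = (
    "c[N+](=O)[O-]",            # nitroaromatic
    "c[OX2H]",                  # phenolic hydroxyl
    "c(C(=O)O[CX4])c(C(=O)O[CX4])",  # aromatic ortho-diester (phthalate)
)


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters for a labeled synthetic molecule set."""

    n: int = 300
    positive_fraction: float = 0.47
    toxic_motifs: tuple[str, ...] = TOXIC_MOTIFS
    label_noise: float = 0.05
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n < 1:
            raise ValueError("n must be positive")


# fragment grammar ------------------------------------------------------------
#
# Substituents are composed as alkyl-linker x terminal-group products so the
# grammar spans tens of thousands of distinct structures; at benchmark sizes
# (a few hundred molecules) duplicate draws are rare and train/test overlap
# negligible.

_ALKYL = ("C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC")
_TERMINAL = ("", "O", "OC", "N(C)C", "Cl", "F", "C(=O)C", "C#N")


def _branch_pool() -> tuple[str, ...]:
    pool = ["", "F", "Cl", "OC"]
    for alk in _ALKYL:
        for term in _TERMINAL:
            pool.append(alk + term)
    return tuple(pool)


_BRANCHES = _branch_pool()


def _pick(rng, options):
    return options[rng.integers(len(options))]


def _paren(sub: str) -> str:
    return f"({sub})" if sub else ""


def _toxic_smiles(rng: np.random.Generator) -> str:
    """One molecule carrying at least one of the three toxic motif families."""
    family = rng.integers(3)
    r1, r2 = _pick(rng, _BRANCHES), _pick(rng, _BRANCHES)
    if family == 0:      # nitroaromatic
        return f"O=[N+]([O-])c1ccc{_paren(r1)}c{_paren(r2)}c1"
    if family == 1:      # phenolic hydroxyl
        return f"Oc1ccc{_paren(r1)}c{_paren(r2)}c1"
    # phthalate-like aromatic ortho-diester with variable ester chains
    a1, a2 = _pick(rng, _ALKYL), _pick(rng, _ALKYL)
    return f"O=C(O{a1})c1cc{_paren(r1)}ccc1C(=O)O{a2}"


def _neutral_smiles(rng: np.random.Generator) -> str:
    """One motif-free molecule from the neutral fragment pool.

    Ring substituents never place a bare hydroxyl on an aromatic carbon, and
    at most one ester is attached, so no toxic motif can arise; a
    substructure audit in the generator double-checks this.
    """
    kind = rng.integers(5)
    r1, r2 = _pick(rng, _BRANCHES), _pick(rng, _BRANCHES)
    a1, a2 = _pick(rng, _ALKYL), _pick(rng, _ALKYL)
    if kind == 0:        # substituted benzene
        return f"{a1}c1ccc{_paren(r1)}c{_paren(r2)}c1"
    if kind == 1:        # substituted cyclohexane
        return f"{a1}C1CCC{_paren(r1)}CC1"
    if kind == 2:        # substituted pyridine
        return f"{a1}c1ccc{_paren(r1)}nc1"
    if kind == 3:        # dialkyl amide
        return f"{a1}C(=O)N({a2}){_pick(rng, _ALKYL)}"
    # single aliphatic ester or ether
    link = "C(=O)O" if rng.random() < 0.5 else "O"
    return f"{a1}{link}{a2}"


def _matches_any_motif(smiles: str, motifs) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return any(mol.HasSubstructMatch(Chem.MolFromSmarts(p)) for p in motifs)


def gen_toy_molecules(spec: SynthSpec) -> list[MoleculeRecord]:
    """Generate a labeled, standardized synthetic molecule set.

    Exactly ``round(n * positive_fraction)`` records carry label 1.  With
    probability ``1 - label_noise`` a molecule's structure class matches its
    label; otherwise the opposite class's grammar is used, emulating
    annotation noise.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.positive_fraction))
    labels = np.array([1] * n_pos + [0] * (spec.n - n_pos))
    rng.shuffle(labels)
    records = []
    for i, label in enumerate(labels):
        structure_class = label
        if rng.random() < spec.label_noise:
            structure_class = 1 - label
        for _ in range(100):
            raw = (_toxic_smiles(rng) if structure_class == 1
                   else _neutral_smiles(rng))
            # neutral pool must stay motif-free (e.g. no accidental phenol)
            if structure_class == 0 and _matches_any_motif(raw, spec.toxic_motifs):
                continue
            std = standardize_record(raw)
            if not isinstance(std, Rejection):
                break
        else:  # pragma: no cover - grammar always yields valid molecules
            raise RuntimeError("fragment grammar failed to produce a molecule")
        records.append(MoleculeRecord(id=f"syn{i:04d}", smiles=std,
                                      label=int(label), source="synthetic"))
    return records


# descriptor tables -----------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    zero_fraction: float
    target_entropy_bits: float

    def __post_init__(self):
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be in [0, 1]")


def _entropy_of(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _counts_for_entropy(n_total: int, n_zero: int, target: float, bins: int,
                        ) -> np.ndarray:
    """Bin occupation counts hitting `target` bits within 0.1.

    Zeros sit in bin 0; remaining mass interpolates between all-in-bin-0
    (entropy 0) and uniform over all bins, then a greedy one-count exchange
    refines the rounded distribution.  Raises if the target is unreachable.
    """
    z = n_zero / n_total

    def probs(theta: float) -> np.ndarray:
        p = np.full(bins, theta / bins)
        p[0] += 1.0 - theta
        return p

    theta_max = min(1.0, bins * (1.0 - z) / (bins - 1))
    lo, hi = 0.0, theta_max
    for _ in range(200):
        mid = (lo + hi) / 2
        h = _entropy_of(probs(mid) * n_total)
        if h < target:
            lo = mid
        else:
            hi = mid
    p = probs((lo + hi) / 2)
    counts = np.floor(p * n_total).astype(int)
    counts[0] += n_total - counts.sum()
    counts[0] = max(counts[0], n_zero)
    # the top bin must be occupied so the observed range spans all bins
    floors = np.zeros(bins, dtype=int)
    floors[0] = max(n_zero, 1)  # bin 0 anchors the bottom of the range
    floors[bins - 1] = 1        # top bin anchors the top
    if counts[bins - 1] == 0:
        src = int(np.argmax(counts - floors))
        counts[src] -= 1
        counts[bins - 1] += 1
    # greedy repair: move single counts to reduce |H - target|
    for _ in range(4 * n_total):
        err = abs(_entropy_of(counts) - target)
        if err <= 0.08:
            break
        best = None
        for src in range(bins):
            if counts[src] <= floors[src]:
                continue
            for dst in range(bins):
                if dst == src:
                    continue
                trial = counts.copy()
                trial[src] -= 1
                trial[dst] += 1
                e = abs(_entropy_of(trial) - target)
                if best is None or e < best[0]:
                    best = (e, trial)
        if best is None or best[0] >= err:
            break
        counts = best[1]
    if abs(_entropy_of(counts) - target) > 0.1:
        raise ValueError(
            f"infeasible column spec: zero_fraction {z:.2f} with target "
            f"entropy {target:.2f} bits cannot be realized over {bins} bins "
            f"at n={n_total}")
    return counts


def gen_descriptor_table(n_rows: int, column_specs, seed: int = 42,
                         bins: int = 10) -> pd.DataFrame:
    """Descriptor table with controlled per-column zero fraction and entropy.

    Each column realizes its requested zero fraction exactly (rounded to a
    count) and its Shannon entropy within +-0.1 bits under ``bins``
    equal-width bins.  Column order and values are deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for ci, cs in enumerate(column_specs):
        if not isinstance(cs, ColumnSpec):
            cs = ColumnSpec(*cs) if isinstance(cs, (tuple, list)) else \
                ColumnSpec(cs["zero_fraction"], cs["target_entropy_bits"])
        name = f"D{ci:03d}"
        n_zero = int(round(cs.zero_fraction * n_rows))
        if n_zero == n_rows:
            data[name] = np.zeros(n_rows)
            continue
        counts = _counts_for_entropy(n_rows, n_zero, cs.target_entropy_bits,
                                     bins)
        # bin-centre values: zeros sit at 0.0 in bin 0, bin j contributes
        # j + 0.5; with the top bin occupied, equal-width binning of the
        # observed range reproduces the designed occupation exactly
        vals = [0.0] * n_zero
        vals += [0.5] * (counts[0] - n_zero)
        for j in range(1, bins):
            vals += [j + 0.5] * counts[j]
        vals = np.array(vals, dtype=np.float64)
        rng.shuffle(vals)
        achieved = shannon_entropy(vals, bins=bins)
        if abs(achieved - cs.target_entropy_bits) > 0.1:
            raise ValueError(
                f"column {name}: achieved entropy {achieved:.3f} misses "
                f"target {cs.target_entropy_bits:.3f}")
        data[name] = vals
    return pd.DataFrame(data, index=[f"m{i:04d}" for i in range(n_rows)])
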