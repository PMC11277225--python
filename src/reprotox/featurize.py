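"""Fingerprints, 2D descriptors, the two-stage descriptor filter, Tanimoto
similarity, and the radar-chart physicochemical profile.

The descriptor filter reproduces a two-stage variable screen: first drop
descriptors that are more than 90% exact zeros across the dataset, then drop
descriptors whose Shannon entropy under a 10-bin equal-width discretization
falls below 2.5 bits.  Both comparisons are strict, so boundary columns are
kept.  The filters are scikit-learn transformers and compose in a Pipeline;
they are engine-agnostic and accept any externally computed descriptor table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .standardize import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BitFingerprint", "FilterReport", "PropertyProfile",
    "morgan_fingerprint", "maccs_fingerprint", "fingerprint_matrix",
    "tanimoto", "compute_descriptors", "shannon_entropy",
    "zero_fraction_filter", "entropy_filter",
    "ZeroFractionFilter", "EntropyFilter", "property_profile",
]


# --------------------------------------------------------------- fingerprints

@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: np.ndarray          # uint8 0/1 vector
    scheme: str               # "morgan" | "maccs"
    nbits: int
    radius: int | None = None  # morgan only

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.shape != (self.nbits,):
            raise ValueError("bit vector length does not match nbits")

    def popcount(self) -> int:
        return int(self.bits.sum())


def _as_mol(record) -> Chem.Mol:
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, Chem.Mol):
        mol = record
    else:
        mol = Chem.MolFromSmiles(str(record))
    if mol is None:
        raise ValueError(f"invalid molecule: {record!r}")
    return mol


def morgan_fingerprint(record, radius: int = 2, nbits: int = 2048) -> BitFingerprint:
    """Circular (Morgan/ECFP) fingerprint, radius 2 on 2048 bits by default."""
    mol = _as_mol(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    for b in gen.GetFingerprint(mol).GetOnBits():
        arr[b] = 1
    return BitFingerprint(bits=arr, scheme="morgan", nbits=nbits, radius=radius)


def maccs_fingerprint(record) -> BitFingerprint:
    """166-key MACCS fingerprint (RDKit's unused bit 0 dropped)."""
    mol = _as_mol(record)
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(166, dtype=np.uint8)
    for b in bv.GetOnBits():
        if b >= 1:
            arr[b - 1] = 1
    return BitFingerprint(bits=arr, scheme="maccs", nbits=166)


def fingerprint_matrix(records, scheme: str = "morgan", radius: int = 2,
                       nbits: int = 2048) -> np.ndarray:
    """Stacked 0/1 fingerprint matrix (molecules x bits)."""
    if scheme == "morgan":
        fps = [morgan_fingerprint(r, radius=radius, nbits=nbits) for r in records]
    elif scheme == "maccs":
        fps = [maccs_fingerprint(r) for r in records]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return np.stack([fp.bits for fp in fps]).astype(np.float64)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined to have similarity 1.0.
    """
    if a.scheme != b.scheme or a.nbits != b.nbits:
        raise ValueError("fingerprints must share scheme and length")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


# ---------------------------------------------------------------- descriptors

def _descriptor_functions():
    # the full RDKit 2D descriptor list; fixed and versioned by rdkit itself
    return list(Descriptors.descList)


def compute_descriptors(records: list) -> pd.DataFrame:
    """Named 2D descriptor table, one row per record.

    Descriptors that fail or return non-finite values for a molecule are
    imputed as 0 and logged, so the table never carries missing values.
    """
    if not records:
        raise ValueError("compute_descriptors requires a non-empty record list")
    funcs = _descriptor_functions()
    names = [n for n, _ in funcs]
    rows, ids = [], []
    for rec in records:
        mol = _as_mol(rec)
        ids.append(rec.id if isinstance(rec, MoleculeRecord) else str(rec))
        row = []
        for name, fn in funcs:
            try:
                v = float(fn(mol))
            except Exception:
                v = np.nan
            if not np.isfinite(v):
                logger.info("descriptor %s failed for %s; imputed 0", name, ids[-1])
                v = 0.0
            row.append(v)
        rows.append(row)
    return pd.DataFrame(rows, index=ids, columns=names)


# -------------------------------------------------------------------- filters

@dataclass
class FilterReport:
    """Outcome of the two-stage descriptor screen."""

    dropped_zero: list[str] = field(default_factory=list)
    dropped_entropy: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    zero_threshold: float = 0.9
    entropy_threshold: float = 2.5
    bin_count: int = 10

    def validate(self, all_names) -> None:
        groups = (set(self.dropped_zero), set(self.dropped_entropy), set(self.kept))
        union = set().union(*groups)
        if union != set(all_names):
            raise ValueError("filter report does not cover all columns")
        if sum(len(g) for g in groups) != len(union):
            raise ValueError("filter report groups overlap")


def shannon_entropy(column, bins: int = 10) -> float:
    """Shannon entropy in bits of a column under equal-width binning.

    Values are assigned to ``bins`` equal-width bins spanning [min, max]
    (the maximum falls in the last bin); H = -sum p_i log2 p_i over nonempty
    bins.  A constant column has zero entropy.  Invariant under affine
    rescaling of the column.
    """
    x = np.asarray(column, dtype=np.float64)
    if x.size < 1:
        raise ValueError("column must be non-empty")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.intp)
    idx[idx == bins] = bins - 1  # the maximum belongs to the last bin
    counts = np.bincount(idx, minlength=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def zero_fraction_filter(table: pd.DataFrame, threshold: float = 0.9,
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop columns whose fraction of exact zeros strictly exceeds threshold."""
    f = ZeroFractionFilter(threshold=threshold).fit(table)
    return f.transform(table), f.report_


def entropy_filter(table: pd.DataFrame, threshold: float = 2.5,
                   bins: int = 10, prior: FilterReport | None = None,
                   ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop columns with Shannon entropy strictly below threshold.

    Meant to run after :func:`zero_fraction_filter`; pass its report via
    ``prior`` so the combined report records both stages.
    """
    f = EntropyFilter(threshold=threshold, bins=bins).fit(table)
    out = f.transform(table)
    report = FilterReport(
        dropped_zero=list(prior.dropped_zero) if prior else [],
        dropped_entropy=f.report_.dropped_entropy,
        kept=f.report_.kept,
        zero_threshold=prior.zero_threshold if prior else 0.9,
        entropy_threshold=threshold, bin_count=bins)
    return out, report


class ZeroFractionFilter(BaseEstimator, TransformerMixin):
    """Sparsity screen: drops descriptors that are mostly exact zeros.

    Parameters
    ----------
    threshold : float, default 0.9
        Columns with zero-fraction strictly greater than this are dropped.
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        zf = (X.to_numpy(dtype=np.float64) == 0.0).mean(axis=0)
        names = list(X.columns)
        self.keep_ = [n for n, z in zip(names, zf) if z <= self.threshold]
        self.report_ = FilterReport(
            dropped_zero=[n for n in names if n not in set(self.keep_)],
            kept=list(self.keep_), zero_threshold=self.threshold)
        self.n_features_in_ = len(names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "keep_")
        return pd.DataFrame(X)[self.keep_]


class EntropyFilter(BaseEstimator, TransformerMixin):
    """Information screen: drops descriptors with low Shannon entropy.

    Columns whose entropy under ``bins`` equal-width bins is strictly below
    ``threshold`` bits are dropped.  Apply after :class:`ZeroFractionFilter`.
    """

    def __init__(self, threshold: float = 2.5, bins: int = 10):
        self.threshold = threshold
        self.bins = bins

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        names = list(X.columns)
        self.entropies_ = {n: shannon_entropy(X[n].to_numpy(), bins=self.bins)
                           for n in names}
        self.keep_ = [n for n in names if self.entropies_[n] >= self.threshold]
        self.report_ = FilterReport(
            dropped_entropy=[n for n in names if n not in set(self.keep_)],
            kept=list(self.keep_), entropy_threshold=self.threshold,
            bin_count=self.bins)
        self.n_features_in_ = len(names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "keep_")
        return pd.DataFrame(X)[self.keep_]


# ------------------------------------------------------------ radar properties

@dataclass(frozen=True)
class PropertyProfile:
    """The 13 radar-chart physicochemical properties.

    logS is an ESOL-style estimate and logD an ionization-corrected logP at
    pH 7.4; both are approximate (``approximate`` lists which).
    """

    MW: float
    logP: float
    logS: float
    logD: float
    nHD: int
    nHA: int
    TPSA: float
    nRot: int
    nRing: int
    MaxRing: int
    nHet: int
    nRig: int
    fChar: float
    approximate: tuple[str, ...] = ("logS", "logD")


_ACID_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")      # carboxylic acid
_BASE_SMARTS = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O);!$(Na)]")  # aliphatic amine


def property_profile(record) -> PropertyProfile:
    """Compute the 13-property physicochemical radar profile of a molecule."""
    mol = _as_mol(record)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    nrot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    ri = mol.GetRingInfo()
    nring = ri.NumRings()
    maxring = max((len(r) for r in ri.AtomRings()), default=0)
    narom = rdMolDescriptors.CalcNumAromaticRings(mol)
    # ESOL (Delaney) estimated aqueous solubility, log10 mol/L
    heavy = mol.GetNumHeavyAtoms()
    ap = (sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy
          if heavy else 0.0)
    logs = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * nrot - 0.74 * ap
    # crude pH 7.4 distribution coefficient: acids/bases are mostly ionized,
    # costing roughly 2 log units per strongly ionizable group present
    n_acid = len(mol.GetSubstructMatches(_ACID_SMARTS))
    n_base = len(mol.GetSubstructMatches(_BASE_SMARTS))
    logd = logp - 2.0 * float(n_acid > 0) - 1.0 * float(n_base > 0)
    n_bonds = mol.GetNumBonds()
    return PropertyProfile(
        MW=mw, logP=logp, logS=logs, logD=logd,
        nHD=rdMolDescriptors.CalcNumHBD(mol),
        nHA=rdMolDescriptors.CalcNumHBA(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol),
        nRot=nrot, nRing=nring, MaxRing=maxring,
        nHet=sum(1 for a in mol.GetAtoms()
                 if a.GetAtomicNum() not in (1, 6)),
        nRig=n_bonds - nrot,
        fChar=narom / nring if nring else 0.0,
    )
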