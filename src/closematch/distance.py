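"""Pairwise genetic distances with pairwise deletion.

Three models are supported:

* ``p`` — uncorrected proportion of differing sites,
* ``jc69`` — Jukes–Cantor correction, d = -3/4 ln(1 - 4p/3),
* ``k2p`` — Kimura two-parameter correction,
  d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the observed
  transition and transversion proportions.

Sites where either sequence carries N or a gap are excluded from that pair's
counts (pairwise deletion).  Distances that are undefined — no overlapping
sites, or a saturated pair outside the log domain of the correction — are
carried as NaN and reported per pair, never silently propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import BarcodeLibrary

__all__ = [
    "MODELS",
    "SitePairCounts",
    "DistanceMatrix",
    "site_pair_counts",
    "p_distance",
    "jc69_distance",
    "k2p_distance",
    "distance_from_counts",
    "pairwise_matrix",
    "split_intra_inter",
]

MODELS = ("p", "jc69", "k2p")

# A=0, G=2 are purines (even codes); C=1, T=3 pyrimidines (odd codes), so a
# mismatch is a transition iff both codes share parity.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255, "-": 255}


_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _code in _CODE.items():
    _LUT[ord(_ch)] = _code


def encode(residues: str) -> np.ndarray:
    """Encode a normalized residue string as uint8 codes (255 = missing)."""
    return _LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SitePairCounts:
    """Shared site counts between two aligned sequences after pairwise deletion."""

    compared: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if min(self.compared, self.transitions, self.transversions) < 0:
            raise ValueError("negative site counts")
        if self.transitions + self.transversions > self.compared:
            raise ValueError("more mismatches than compared sites")


def site_pair_counts(a: str, b: str) -> SitePairCounts:
    """Count compared sites, transitions and transversions for one pair."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    xa, xb = encode(a), encode(b)
    valid = (xa != 255) & (xb != 255)
    diff = valid & (xa != xb)
    ts = diff & ((xa & 1) == (xb & 1))
    return SitePairCounts(
        compared=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def p_distance(c: SitePairCounts) -> float:
    """Proportion of compared sites at which the two sequences differ."""
    if c.compared == 0:
        return math.nan
    return (c.transitions + c.transversions) / c.compared


def jc69_distance(c: SitePairCounts) -> float:
    """Jukes–Cantor distance; NaN when p >= 3/4 (outside the log domain)."""
    p = p_distance(c)
    if math.isnan(p):
        return math.nan
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def k2p_distance(c: SitePairCounts) -> float:
    """Kimura two-parameter distance; NaN outside the log domain (saturation)."""
    if c.compared == 0:
        return math.nan
    P = c.transitions / c.compared
    Q = c.transversions / c.compared
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.nan
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


_SCALAR = {"p": p_distance, "jc69": jc69_distance, "k2p": k2p_distance}


def distance_from_counts(c: SitePairCounts, model: str) -> float:
    """Evaluate one model on one pair's site counts."""
    try:
        return _SCALAR[model](c)
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over a library's records.

    ``values[i, j]`` is NaN where the distance is undefined; every such pair
    is listed in ``undefined_pairs`` with its reason (``no_overlap`` or
    ``saturated``).
    """

    ids: list[str]
    values: np.ndarray
    model: str
    undefined_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_matrix(lib: BarcodeLibrary, model: str = "k2p") -> DistanceMatrix:
    """Compute all n(n-1)/2 pairwise distances under one model.

    Undefined pairs (no overlapping sites, or saturation under a corrected
    model) are recorded and set to NaN without aborting.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    n = len(lib)
    X = np.stack([encode(rec.residues) for rec in lib.records])
    present = X != 255
    parity = X & 1
    values = np.zeros((n, n))
    undefined: list[tuple[str, str, str]] = []
    for i in range(n - 1):
        valid = present[i] & present[i + 1 :]
        diff = valid & (X[i] != X[i + 1 :])
        compared = valid.sum(axis=1).astype(float)
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "p":
                d = (ts + tv) / compared
            elif model == "jc69":
                p = (ts + tv) / compared
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                P = ts / compared
                Q = tv / compared
                d = -0.5 * np.log(1.0 - 2.0 * P - Q) - 0.25 * np.log(1.0 - 2.0 * Q)
        d = np.where(np.isfinite(d), d, np.nan)
        for k in np.nonzero(np.isnan(d))[0]:
            j = i + 1 + int(k)
            reason = "no_overlap" if compared[k] == 0 else "saturated"
            undefined.append((lib.ids[i], lib.ids[j], reason))
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(lib.ids), values, model, undefined)


def split_intra_inter(
    m: DistanceMatrix, lib: BarcodeLibrary
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition unordered pairs into intra-, interspecific and undefined.

    Returns three DataFrames with columns (id_a, id_b, distance); undefined
    pairs carry NaN distances and appear only in the third frame.
    """
    if m.ids != lib.ids:
        raise ValueError("distance matrix does not match library")
    intra, inter, undef = [], [], []
    sp = lib.species
    for i in range(m.n - 1):
        for j in range(i + 1, m.n):
            row = (m.ids[i], m.ids[j], m.values[i, j])
            if math.isnan(m.values[i, j]):
                undef.append(row)
            elif sp[i] == sp[j]:
                intra.append(row)
            else:
                inter.append(row)
    cols = ["id_a", "id_b", "distance"]
    return (
        pd.DataFrame(intra, columns=cols),
        pd.DataFrame(inter, columns=cols),
        pd.DataFrame(undef, columns=cols),
    )
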