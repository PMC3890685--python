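"""Synthetic aligned barcode libraries with known ground truth.

The generator emulates the situation the *ad hoc* threshold method is built
for: a reference library whose species form distinct sequence clusters, but
which covers the local fauna incompletely, so that some queries have no
conspecific reference and their best match is necessarily allospecific.

Model: a uniform-random root sequence; one ancestor per species derived from
the root by per-site substitution at rate ``inter_p / 2`` (so that realized
ancestor-to-ancestor divergence is approximately ``inter_p``); each library
sequence derived from its species ancestor by independent per-site
substitution at rate ``intra_p``.  Substitutions are uniform over the three
alternative bases (no transition bias).  Incomplete coverage is emulated by
reducing a fraction of species to a single record.  Optional N-masking
exercises pairwise deletion.  Alignments are generated gap-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .library import BarcodeLibrary, SequenceRecord

__all__ = ["SimParams", "simulate_library", "write_simulation"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Defaults describe a well-separated mid-size library: 20 species of 5
    sequences, 600 aligned sites, ~2% intraspecific and ~20% interspecific
    divergence, with 20% of species represented by a single sequence.
    """

    n_species: int = 20
    seqs_per_species: int | tuple[int, int] = 5
    alignment_length: int = 600
    intra_p: float = 0.01
    inter_p: float = 0.2
    missing_species_fraction: float = 0.2
    n_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0 <= self.intra_p < self.inter_p <= 0.75:
            raise ValueError("require 0 <= intra_p < inter_p <= 0.75")
        if not 0 <= self.missing_species_fraction <= 1:
            raise ValueError("missing_species_fraction must be in [0, 1]")
        if not 0 <= self.n_rate <= 1:
            raise ValueError("n_rate must be in [0, 1]")
        k = self.seqs_per_species
        if isinstance(k, tuple):
            if len(k) != 2 or k[0] < 1 or k[1] < k[0]:
                raise ValueError("seqs_per_species range must be (lo, hi), lo >= 1")
        elif k < 1:
            raise ValueError("seqs_per_species must be >= 1")


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at rate p, uniform over the 3 alternative bases."""
    out = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n)) % 4
    return out


def simulate_library(params: SimParams) -> tuple[BarcodeLibrary, dict]:
    """Generate a library and its ground-truth record.

    The truth record holds the generator parameters, the per-record species
    labels, and which species were reduced to singletons (their removed
    records' labels included), so tests never re-derive ground truth.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    L = params.alignment_length
    root = rng.integers(0, 4, L)
    species_names = [f"Species{_i + 1:03d}" for _i in range(params.n_species)]
    ancestors = [_mutate(root, params.inter_p / 2.0, rng) for _ in species_names]

    ids, labels, seqs = [], [], []
    for name, anc in zip(species_names, ancestors):
        if isinstance(params.seqs_per_species, tuple):
            lo, hi = params.seqs_per_species
            k = int(rng.integers(lo, hi + 1))
        else:
            k = params.seqs_per_species
        for j in range(k):
            ids.append(f"{name}_{j + 1}")
            labels.append(name)
            seqs.append(_mutate(anc, params.intra_p, rng))

    n_missing = int(round(params.missing_species_fraction * params.n_species))
    missing = sorted(
        rng.choice(params.n_species, size=n_missing, replace=False).tolist()
    )
    missing_names = {species_names[i] for i in missing}
    removed_ids = []
    keep = []
    seen: set[str] = set()
    for idx, (rid, lab) in enumerate(zip(ids, labels)):
        if lab in missing_names and lab in seen:
            removed_ids.append(rid)
        else:
            keep.append(idx)
            seen.add(lab)

    records = []
    for idx in keep:
        chars = _BASES[seqs[idx]].copy()
        if params.n_rate > 0:
            chars[rng.random(L) < params.n_rate] = "N"
        records.append(SequenceRecord(ids[idx], labels[idx], "".join(chars)))
    lib = BarcodeLibrary(tuple(records))

    truth = {
        "params": {
            **asdict(params),
            "seqs_per_species": list(params.seqs_per_species)
            if isinstance(params.seqs_per_species, tuple)
            else params.seqs_per_species,
        },
        "species": species_names,
        "singleton_species": sorted(missing_names),
        "removed_ids": removed_ids,
        "record_species": {rec.id: rec.species for rec in records},
        "n_records": len(records),
    }
    return lib, truth


def write_simulation(
    lib: BarcodeLibrary, truth: dict, fasta_path: str | Path, truth_path: str | Path
) -> None:
    """Write the simulated library as FASTA and its ground truth as JSON."""
    from .library import write_fasta_library

    write_fasta_library(lib, fasta_path)
    Path(truth_path).write_text(json.dumps(truth, indent=2) + "\n")
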