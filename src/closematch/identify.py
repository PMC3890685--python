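"""Leave-one-out best-match and best-close-match identification.

Each reference sequence is taken in turn as a query against all other
sequences.  The *best match* is the set of records at minimum defined
distance (ties included).  Under *best match* the query is labelled

* TP — every tied best match is conspecific,
* FP — no tied best match is conspecific,
* FP_AMBIGUOUS — the tied set mixes the correct species with others.

Under *best close match* with threshold t, the best-match label applies when
the best-match distance is <= t; above t the identification is rejected: FN
when a conspecific was in the tied set (a correct assignment ignored), TN
otherwise.  A query with no defined distance to any other record is
UNDEFINED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .library import BarcodeLibrary

__all__ = [
    "TIE_TOL",
    "Outcome",
    "BestMatchResult",
    "RedFlagReport",
    "leave_one_out",
    "classify_best_match",
    "classify_best_close_match",
    "red_flags",
    "results_table",
]

#: Absolute tolerance used to detect tied minimum distances.  Identical site
#: patterns yield bit-identical distances; the tolerance only guards against
#: summation-order noise.
TIE_TOL = 1e-12


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    FP_AMBIGUOUS = "FP_ambiguous"
    TN = "TN"
    FN = "FN"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class BestMatchResult:
    """Nearest-neighbour result for one leave-one-out query."""

    query_id: str
    query_species: str
    bm_distance: float  # NaN when no defined distance exists
    match_ids: tuple[str, ...]
    match_species: frozenset[str]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.bm_distance)

    @property
    def conspecific_in_matches(self) -> bool:
        return self.query_species in self.match_species


def leave_one_out(lib: BarcodeLibrary, m: DistanceMatrix) -> list[BestMatchResult]:
    """Best-match search for every record, self excluded, ties kept."""
    if m.ids != lib.ids:
        raise ValueError("distance matrix does not match library")
    n = m.n
    results = []
    for i in range(n):
        row = m.values[i].copy()
        row[i] = np.nan
        if np.all(np.isnan(row)):
            results.append(
                BestMatchResult(lib.ids[i], lib.species[i], math.nan, (), frozenset())
            )
            continue
        dmin = np.nanmin(row)
        ties = np.nonzero(row <= dmin + TIE_TOL)[0]
        match_ids = tuple(lib.ids[j] for j in ties)
        match_species = frozenset(lib.species[j] for j in ties)
        results.append(
            BestMatchResult(lib.ids[i], lib.species[i], float(dmin), match_ids, match_species)
        )
    return results


def classify_best_match(r: BestMatchResult) -> Outcome:
    """TP / FP / FP_AMBIGUOUS label for an unconditional best-match identification."""
    if not r.match_ids:
        return Outcome.UNDEFINED
    if not r.conspecific_in_matches:
        return Outcome.FP
    if len(r.match_species) > 1:
        return Outcome.FP_AMBIGUOUS
    return Outcome.TP


def classify_best_close_match(r: BestMatchResult, t: float) -> Outcome:
    """Best-close-match label at threshold t (acceptance is d <= t)."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    if not r.match_ids:
        return Outcome.UNDEFINED
    if r.bm_distance <= t:
        return classify_best_match(r)
    return Outcome.FN if r.conspecific_in_matches else Outcome.TN


@dataclass
class RedFlagReport:
    """Matches and species implicated in ambiguous identifications.

    ``matches`` has one row per ambiguous query with the conspecific and
    allospecific members of its tied best-match set; ``species`` counts how
    often each species is involved in an ambiguity.
    """

    matches: pd.DataFrame
    species: pd.DataFrame


def red_flags(lib: BarcodeLibrary, results: list[BestMatchResult]) -> RedFlagReport:
    """Tabulate the tied cross-species matches behind FP_AMBIGUOUS queries."""
    sp_of = {rec.id: rec.species for rec in lib.records}
    rows = []
    counts: dict[str, int] = {}
    for r in results:
        if classify_best_match(r) is not Outcome.FP_AMBIGUOUS:
            continue
        cons = [i for i in r.match_ids if sp_of[i] == r.query_species]
        allo = [i for i in r.match_ids if sp_of[i] != r.query_species]
        rows.append(
            {
                "query_id": r.query_id,
                "query_species": r.query_species,
                "conspecific_matches": ",".join(cons),
                "allospecific_matches": ",".join(allo),
                "distance": r.bm_distance,
            }
        )
        for sp in {r.query_species} | set(r.match_species):
            counts[sp] = counts.get(sp, 0) + 1
    matches = pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "query_species",
            "conspecific_matches",
            "allospecific_matches",
            "distance",
        ],
    )
    species = pd.DataFrame(
        {"species": list(counts), "n_ambiguous_identifications": list(counts.values())}
    )
    return RedFlagReport(matches, species)


def results_table(
    results: list[BestMatchResult], adhoc_threshold: float | None = None
) -> pd.DataFrame:
    """Per-query export: best-match label plus, optionally, the label at a threshold."""
    rows = []
    for r in results:
        row = {
            "query_id": r.query_id,
            "species": r.query_species,
            "bm_distance": r.bm_distance,
            "match_ids": ",".join(r.match_ids),
            "match_species": ",".join(sorted(r.match_species)),
            "best_match_label": classify_best_match(r).value,
        }
        if adhoc_threshold is not None:
            row["label_at_adhoc_threshold"] = classify_best_close_match(
                r, adhoc_threshold
            ).value
        rows.append(row)
    return pd.DataFrame(rows)
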