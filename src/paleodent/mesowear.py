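"""Mesowear-ruler scoring: validation, median aggregation, diet ranges.

The mesowear ruler assigns an ordinal score 0 (high, sharp cusp) to 6
(low, blunt cusp) to the paracone of moderately worn upper molars.
Scores are aggregated by the median (the scale is ordinal) and
interpreted against literature ranges for extant herbivores:
browsers 0–2, mixed-feeders 0.4–2.74, grazers 2.09–5.47 (overlapping
by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from paleodent.datamodel import UNKNOWN, ValidationError, parse_locus

SCORE_MIN, SCORE_MAX = 0, 6
WEAR_STAGE_WINDOW = (4, 7)

DIET_RANGES = {
    "browser": (0.0, 2.0),
    "mixed-feeder": (0.4, 2.74),
    "grazer": (2.09, 5.47),
}


@dataclass(frozen=True)
class MesowearObservation:
    specimen_id: str
    species: str
    locality: str
    locus: str
    cusp: str            # paracone | metacone | other
    wear_stage: int | str
    score: int

    def __post_init__(self) -> None:
        if not (SCORE_MIN <= int(self.score) <= SCORE_MAX):
            raise ValidationError(f"mesowear score {self.score} outside 0–6")


def observation_valid(obs: MesowearObservation) -> tuple[bool, str]:
    """Inclusion gate: paracone of an upper molar at average wear (4–7).

    Returns (valid, reason); the reason names the first failed rule.
    An unknown wear stage fails the wear rule explicitly (missing is
    distinguished from passing).
    """
    if obs.cusp != "paracone":
        return False, f"cusp rule: scored cusp must be the paracone, got {obs.cusp!r}"
    locus = parse_locus(obs.locus)
    if not (locus.is_molar and locus.is_upper):
        return False, f"upper-molar rule: locus {obs.locus!r} is not an upper molar"
    if obs.wear_stage == UNKNOWN:
        return False, "wear rule: wear stage unknown"
    lo, hi = WEAR_STAGE_WINDOW
    if not (lo <= int(obs.wear_stage) <= hi):
        return False, f"wear rule: stage {obs.wear_stage} outside [{lo}, {hi}]"
    return True, "ok"


def aggregate_median(scores: Sequence[float]) -> float | None:
    """Median score; half-integers arise for even n.  Empty → None."""
    if len(scores) == 0:
        return None
    return float(np.median(np.asarray(scores, dtype=float)))


def classify_diet(median_score: float) -> set[str]:
    """Every diet category whose literature range contains the value."""
    if not (SCORE_MIN <= median_score <= SCORE_MAX):
        raise ValidationError(f"median score {median_score} outside the 0–6 ruler")
    return {name for name, (lo, hi) in DIET_RANGES.items() if lo <= median_score <= hi}


def summarize(observations: Iterable[MesowearObservation] | pd.DataFrame
              ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Species × locality mesowear summary after validity filtering.

    Returns (summary frame, rejected list of (specimen_id, reason)).
    """
    if isinstance(observations, pd.DataFrame):
        observations = [
            MesowearObservation(
                specimen_id=str(r["specimen_id"]), species=str(r["species"]),
                locality=str(r["locality"]), locus=str(r["locus"]),
                cusp=str(r["cusp"]),
                wear_stage=(r["wear_stage"] if str(r["wear_stage"]) == UNKNOWN
                            else int(r["wear_stage"])),
                score=int(r["score"]))
            for _, r in observations.iterrows()
        ]
    rejected: list[tuple[str, str]] = []
    kept: list[MesowearObservation] = []
    for obs in observations:
        ok, reason = observation_valid(obs)
        (kept if ok else rejected).append(obs if ok else (obs.specimen_id, reason))
    rows = []
    frame = pd.DataFrame([{
        "species": o.species, "locality": o.locality, "score": o.score} for o in kept])
    if frame.empty:
        return pd.DataFrame(columns=["species", "locality", "n", "median_score",
                                     "diet_categories"]), rejected
    for (species, locality), grp in frame.groupby(["species", "locality"], sort=True):
        med = aggregate_median(grp["score"].tolist())
        rows.append({
            "species": species, "locality": locality, "n": len(grp),
            "median_score": med,
            "diet_categories": "|".join(sorted(classify_diet(med))),
        })
    return pd.DataFrame(rows), rejected
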